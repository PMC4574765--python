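<?xml version="1.0" encoding="UTF-8"?>
<!--
  Synthetic stand-in for the KEGG renin-angiotensin system pathway
  (hsa04614), hand-built for offline tests.  Entry ids, gene symbols and
  KEGG gene identifiers follow the real pathway's conventions (including
  CPA3, hsa:1359) but the node set, coordinates and edge set are a small
  fabricated subset, not a copy of the KEGG file.
-->
<pathway name="path:hsa04614" org="hsa" number="04614"
         title="Renin-angiotensin system"
         image="https://example.invalid/hsa04614.png">
  <entry id="1" name="hsa:183" type="gene">
    <graphics name="AGT, ANHU, SERPINA8" x="120" y="180" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="2" name="hsa:5972" type="gene">
    <graphics name="REN, HNFJ2" x="210" y="180" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="3" name="hsa:1636" type="gene">
    <graphics name="ACE, ACE1, CD143, DCP" x="320" y="180" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="4" name="hsa:185" type="gene">
    <graphics name="AGTR1, AG2S, AGTR1B" x="430" y="140" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="5" name="hsa:1359" type="gene">
    <graphics name="CPA3, MC-CPA" x="320" y="260" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="6" name="hsa:1511" type="gene">
    <graphics name="CTSG, CG" x="210" y="260" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="7" name="hsa:1215" type="gene">
    <graphics name="CMA1, CYH, MCT1" x="430" y="260" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="8" name="cpd:C00873" type="compound">
    <graphics name="C00873" x="265" y="220" width="8" height="8" type="circle"/>
  </entry>
  <entry id="9" name="path:hsa04924" type="map">
    <graphics name="Renin secretion" x="90" y="80" width="110" height="25" type="roundrectangle"/>
  </entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="compound" value="8"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="3" entry2="4" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="6" entry2="5" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="7" entry2="4" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
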