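# Methods

## The model and its assumptions

The analysis core treats a bulk expression experiment as a genes ×
samples matrix of log2 intensities with a two-level group factor — a
case group and an explicitly designated reference group. No
normalization, batch correction or paired structure is modeled; the
matrix is taken as already preprocessed, and genes are analyzed
independently of one another.

Per gene the package reports:

- **log2 fold change** `mean(case) − mean(reference)`. The log2
  difference (rather than a linear ratio) is the convention that makes 0
  the neutral point of the diverging color map; `linear_ratio` converts
  to `2^FC` for display.
- **two-sample t-test**, Welch by default. Welch does not assume equal
  group variances and is the safer default for group comparisons of
  array intensities; a pooled-variance Student variant is available via
  `variant="student"` for users who want the classical test.
- **Benjamini–Hochberg q-values**, step-up rule, always over the full
  gene universe of the loaded dataset. Adjusting within a queried subset
  would make a gene's q-value depend on what else happened to be in the
  query; computing once dataset-wide and subsetting keeps every endpoint
  consistent with every other.

BH and the t-tests are delegated to `statsmodels` and `scipy`
respectively behind the module's own validated surface; the test suite
checks both against independent re-implementations (a literal O(n²)
step-up transcription, and the closed-form Welch statistic with the
t survival function).

### Degenerate inputs

Zero within-group variance in both groups leaves the t-statistic
undefined. Rather than emit NaN — which is not a JSON number and
poisons downstream arithmetic — the package uses fixed conventions:
equal means → t = 0, p = 1 (no evidence of change); different means →
p = 0 with t = ±∞ carrying the sign of the difference (a shift with no
observed noise). Only p and q reach the JSON endpoints. Genes absent
from the dataset are `null` at every query operation, never an error:
pathway gene sets routinely exceed what is on an array.

## Pathway graphs

KGML `entry` elements become typed nodes (`gene`, `compound`, `map`,
`group`, `ortholog`, `enzyme`; anything unrecognized maps to `other`
because KGML dialects drift across KEGG releases). Graphics `x`/`y` are
kept verbatim as node centers in the background image's pixel space
(origin top-left, y downward, no rescaling) so overlays align with the
KEGG-drawn image. An entry's space-separated KEGG ids are all retained;
the display label is the first comma-separated alias of the graphics
name, matching KEGG rendering conventions.

Open representation choices, decided here: `group` entries stay as
nodes carrying `member_ids` while their members remain independent
nodes (lossless); reactions with several substrates/products expand to
the full substrate→product cross-product so the edge model stays
uniform; relations or reactions whose endpoints do not resolve to a
parsed entry are dropped rather than failing the whole document.
The JSON view document is a faithful projection — re-importing it
reproduces the graph exactly, which the tests exploit as a round-trip
oracle.

## Overlay

Fill color interpolates linearly in RGB from white at FC = 0 toward
blue `#0571B0` (down) or red `#CA0020` (up), saturating at ±`limit`
(default 2.0 log2 units — typical microarray effects live well inside
that range; values beyond clamp). The pair is a colorblind-safer
diverging palette. Genes with no statistics get neutral gray. The
significance frame (`#33A02C`) appears when q ≤ α, boundary inclusive,
α default 0.05. When one node lists several measured genes the
representative is the minimum-q gene (ties broken lexicographically):
the strongest signal on the node is what a researcher should notice.

## Service, cache, CLI

The REST layer is deliberately thin: every payload is value-identical
to the corresponding library call, multi-gene queries use the KEGG-style
`+` separator (commas are rejected with a hint), and trailing-slash
variants resolve. It is a plain WSGI application served by the standard
library's `wsgiref`; default port 8888. Statistics are computed once at
startup per dataset, so identical requests return identical bodies.

The KEGG client fetches through an injected callable (path → bytes),
which is how the whole system runs offline: tests and examples inject
fixture-backed or refusing fetchers, deployments inject the real HTTP
transport. Every response is cached on disk under the percent-encoded
resource path (injective and transparent); entries never expire
automatically — pathway payloads change rarely and pinning favors
reproducibility — and `purge-cache` removes them explicitly.

The CLI exposes the same operations as batch subcommands (`parse`,
`stats`, `overlay`, `simulate`, `serve`, `purge-cache`) with exit codes
0/2/3/4 for success/validation/I-O/network failures.

## Synthetic data

The generator emulates a two-group log2-intensity experiment: gene
baselines `b_g ~ Normal(7, 2)` (a rough log2-microarray range),
reference samples `Normal(b_g, σ)`, case samples `Normal(b_g + δ·1[g ∈
DE], σ)`, with defaults δ = 2, σ = 1, 10 samples per group and a
configurable DE fraction. One `numpy` Generator seeded explicitly
drives all draws — fixed seed, byte-identical output — and written
datasets carry a JSON manifest of the planted truth. The KGML generator
emits valid pathway documents whose gene entries can draw their ids
from a dataset's gene universe, so pathway and dataset fixtures join
the way a real pathway joins a real array.

What the generator does **not** emulate: probe effects, batch
structure, missingness, inter-gene correlation, heavy-tailed noise.
Passing calibration on these fixtures therefore shows the statistics
behave correctly under independent Gaussian noise, not that real-array
artifacts are handled.

## Verification sizes and numerical choices

The acceptance script and tests use problem sizes chosen to give stable
Monte-Carlo estimates at desk scale: 1000-vector oracle sweeps for BH,
500 random group pairs for Welch, 100 replicates of a 1000-gene /
50-DE / n=10-per-group design for FDR control and power (the
Monte-Carlo SE of mean FDP is then ≈ 0.004, small against the 0.05
target), 200 replicates of a 500-gene global-null design for the
any-discovery rate, and 100 generated pathways for the round-trip
check. Oracle agreement is asserted to 1e-12 absolute (BH) and 1e-10
relative (Welch p); color arithmetic rounds to integer RGB channels at
the end only.

## Known limitations

- Two groups only; no paired designs, covariates or moderated
  (empirical-Bayes) variance estimators.
- KGML writing exists only to the extent the generator needs; the
  package is not a general KGML editor.
- The cache stores payloads verbatim with no integrity metadata beyond
  the filename key.
- The service is read-only, unauthenticated HTTP intended to sit behind
  whatever ingress the deployment provides.
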