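"""Map per-gene statistics onto pathway-node visual attributes.

Fill color encodes the log2 fold change on a diverging blue–white–red
scale (down-regulated → blue, 0 → white, up-regulated → red, linear in
RGB, clamped at ±``limit``); a colored frame marks genes whose BH
q-value reaches the significance level α (boundary inclusive).  Nodes
whose KEGG ids are absent from the dataset get a neutral gray fill and
no frame — absence is data, not an error.

Defaults: blue ``#0571B0`` / red ``#CA0020`` (a colorblind-safer
diverging pair), ``limit = 2.0`` log2 units (covers typical microarray
effect ranges), α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kgml import NodeType, PathwayGraph
from .stats import GeneStatistics

__all__ = [
    "DOWN_COLOR",
    "UP_COLOR",
    "NEUTRAL_COLOR",
    "FRAME_COLOR",
    "OverlayRecord",
    "OverlayStyle",
    "fold_change_to_color",
    "significance_frame",
    "build_overlay",
]

DOWN_COLOR = "#0571B0"
UP_COLOR = "#CA0020"
NEUTRAL_COLOR = "#BEBEBE"
FRAME_COLOR = "#33A02C"
WHITE = "#FFFFFF"


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def _rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def fold_change_to_color(
    log2_fc: float | None,
    limit: float = 2.0,
    down_color: str = DOWN_COLOR,
    up_color: str = UP_COLOR,
) -> str:
    """Diverging fill color for a log2 fold change.

    Linear RGB interpolation white→endpoint, reaching the full endpoint
    color at ±``limit`` and clamping beyond; ``None`` (gene not measured)
    maps to neutral gray.
    """
    if limit <= 0:
        raise ValueError(f"limit must be positive, got {limit}")
    if log2_fc is None:
        return NEUTRAL_COLOR
    frac = min(abs(log2_fc) / limit, 1.0)
    if frac == 0.0:
        return WHITE
    endpoint = _hex_to_rgb(up_color if log2_fc > 0 else down_color)
    white = _hex_to_rgb(WHITE)
    mixed = tuple(
        round(w + frac * (e - w)) for w, e in zip(white, endpoint)
    )
    return _rgb_to_hex(mixed)  # type: ignore[arg-type]


def significance_frame(
    q_value: float | None,
    alpha: float = 0.05,
    frame_color: str = FRAME_COLOR,
) -> str | None:
    """Frame color when the q-value reaches α (inclusive), else ``None``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if q_value is None or q_value > alpha:
        return None
    return frame_color


@dataclass(frozen=True)
class OverlayRecord:
    entry_id: str
    fill_color: str
    frame_color: str | None
    source_gene: str | None
    log2_fc: float | None
    q_value: float | None


@dataclass
class OverlayStyle:
    """Per-node visual attributes for one pathway, keyed by entry id."""

    alpha: float
    limit: float
    records: dict[str, OverlayRecord] = field(default_factory=dict)

    def framed_entry_ids(self) -> list[str]:
        return [r.entry_id for r in self.records.values() if r.frame_color]

    def to_json_document(self) -> dict:
        return {
            "alpha": self.alpha,
            "limit": self.limit,
            "styles": {
                r.entry_id: {
                    "fill": r.fill_color,
                    "frame": r.frame_color,
                    "source_gene": r.source_gene,
                    "log2_fc": r.log2_fc,
                    "q_value": r.q_value,
                }
                for r in self.records.values()
            },
        }


def build_overlay(
    graph: PathwayGraph,
    stats: list[GeneStatistics] | dict[str, GeneStatistics],
    alpha: float = 0.05,
    limit: float = 2.0,
) -> OverlayStyle:
    """Style every node of a pathway from per-gene statistics.

    A gene node may list several KEGG ids; its representative is the gene
    with the smallest q-value (ties broken by lexicographically smallest
    gene id), so the strongest signal on the node is what gets colored.
    Non-gene nodes — and gene nodes none of whose ids were measured —
    receive the neutral fill and no frame.
    """
    if not isinstance(stats, dict):
        stats = {s.gene_id: s for s in stats}
    style = OverlayStyle(alpha=alpha, limit=limit)
    for node in graph.nodes:
        chosen: GeneStatistics | None = None
        if node.node_type is NodeType.GENE:
            measured = [stats[g] for g in node.kegg_ids if g in stats]
            if measured:
                chosen = min(measured, key=lambda s: (s.q_value, s.gene_id))
        if chosen is None:
            style.records[node.entry_id] = OverlayRecord(
                node.entry_id, NEUTRAL_COLOR, None, None, None, None
            )
        else:
            style.records[node.entry_id] = OverlayRecord(
                node.entry_id,
                fold_change_to_color(chosen.log2_fc, limit),
                significance_frame(chosen.q_value, alpha),
                chosen.gene_id,
                chosen.log2_fc,
                chosen.q_value,
            )
    return style
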