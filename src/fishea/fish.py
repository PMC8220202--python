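"""Per-nucleus FISH signal classification and per-sample fusion calling.

Dual-color FISH for translocation detection labels the breakpoint regions of
two chromosomes in red and green.  In a diploid nucleus with intact
chromosomes each probe gives two signals of its color; a break within the
probed region yields a third signal of one color; juxtaposition of the two
loci by a translocation superimposes a red and a green signal into one
co-localized (yellow) fusion signal.  This module operates on observer
counted signal triples (red, green, fusion) per nucleus — spot detection and
colocalization are assumed resolved upstream.

Classification precedence (total over all nonnegative count triples):

1. any fusion signal            -> ``fusion_positive``
2. exactly 2 red and 2 green    -> ``normal``
3. >= 3 of either color         -> ``gain_or_break``
4. otherwise (< 2 of a color)   -> ``uninformative``

A fusion signal outranks extra same-color signals because the co-localized
signal is the positive event for translocation, while three same-color
signals are ambiguous between chromosome gain and a fusion-less break.
``uninformative`` covers truncated nuclei (4-5 um tissue sections routinely
slice nuclei) and is excluded from the denominator when deciding whether
enough cells were scored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CellSignal",
    "CellCategory",
    "ProbeSet",
    "DEFAULT_PROBE_SETS",
    "SampleResult",
    "classify_cell",
    "call_sample",
    "screen_probe_sets",
]


class CellCategory(str, Enum):
    NORMAL = "normal"
    GAIN_OR_BREAK = "gain_or_break"
    FUSION_POSITIVE = "fusion_positive"
    UNINFORMATIVE = "uninformative"


CATEGORIES = tuple(c.value for c in CellCategory)


@dataclass(frozen=True)
class CellSignal:
    """Signal counts for one nucleus: red, green, and co-localized (yellow)."""

    red: int
    green: int
    fusion: int = 0

    def __post_init__(self) -> None:
        for name in ("red", "green", "fusion"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} count must be a nonnegative integer, got {v!r}")


@dataclass(frozen=True)
class ProbeSet:
    """A dual-color probe pair: (red locus, green locus) as band labels."""

    id: str
    red_locus: str
    green_locus: str


#: The three shipped breakpoint probe pairs of the esophageal adenocarcinoma
#: FISH panel, covering the three pairwise fusions of 2p22, 10q22 and 16q22.
DEFAULT_PROBE_SETS: dict[str, ProbeSet] = {
    "set1": ProbeSet("set1", red_locus="2p22", green_locus="16q22"),
    "set2": ProbeSet("set2", red_locus="2p22", green_locus="10q22"),
    "set3": ProbeSet("set3", red_locus="10q22", green_locus="16q22"),
}


@dataclass(frozen=True)
class SampleResult:
    """Aggregate call for one (sample, probe set) hybridization."""

    sample_id: str
    probe_set: str
    n_cells_scored: int
    tallies: Mapping[str, int]
    call: str  # positive | negative | insufficient_cells

    @property
    def n_informative(self) -> int:
        return self.n_cells_scored - self.tallies.get(CellCategory.UNINFORMATIVE.value, 0)


def classify_cell(s: CellSignal) -> CellCategory:
    """Classify one nucleus by its (red, green, fusion) signal counts.

    >>> classify_cell(CellSignal(2, 2, 0)).value
    'normal'
    >>> classify_cell(CellSignal(3, 2, 0)).value
    'gain_or_break'
    >>> classify_cell(CellSignal(2, 2, 1)).value
    'fusion_positive'
    """
    if s.fusion >= 1:
        return CellCategory.FUSION_POSITIVE
    if s.red == 2 and s.green == 2:
        return CellCategory.NORMAL
    if s.red >= 3 or s.green >= 3:
        return CellCategory.GAIN_OR_BREAK
    return CellCategory.UNINFORMATIVE


def call_sample(
    cells: Sequence[CellSignal],
    min_cells: int = 25,
    min_fusion_cells: int = 2,
    sample_id: str = "",
    probe_set: str = "",
) -> SampleResult:
    """Call one hybridization positive/negative for the translocation fusion.

    Every cell is classified; cells in the ``uninformative`` category are
    excluded from the informative denominator.  If fewer than ``min_cells``
    informative cells were scored the call is ``insufficient_cells`` (25 is
    the conventional minimum enumeration depth per hybridization).  Otherwise
    the sample is positive iff at least ``min_fusion_cells`` nuclei carry a
    fusion signal; requiring more than one guards against rare spurious
    red/green superimposition in sectioned tissue.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if min_fusion_cells < 1:
        raise ValueError("min_fusion_cells must be >= 1")
    tallies = Counter({c: 0 for c in CATEGORIES})
    for s in cells:
        tallies[classify_cell(s).value] += 1
    n = len(cells)
    informative = n - tallies[CellCategory.UNINFORMATIVE.value]
    if informative < min_cells:
        call = "insufficient_cells"
    elif tallies[CellCategory.FUSION_POSITIVE.value] >= min_fusion_cells:
        call = "positive"
    else:
        call = "negative"
    return SampleResult(
        sample_id=sample_id,
        probe_set=probe_set,
        n_cells_scored=n,
        tallies=dict(tallies),
        call=call,
    )


def screen_probe_sets(
    cells: pd.DataFrame,
    min_cells: int = 25,
    min_fusion_cells: int = 2,
    probe_sets: Mapping[str, ProbeSet] | None = None,
) -> pd.DataFrame:
    """Call every (sample, probe set) group of a FISH count table.

    Parameters
    ----------
    cells
        Long-format table with columns ``sample_id, probe_set, red, green,
        fusion`` (one row per nucleus; a ``cell_index`` column is allowed and
        ignored).
    probe_sets
        Known probe-set ids; defaults to the three shipped breakpoint pairs.
        A row referencing an unknown id raises ``KeyError``.

    Returns
    -------
    DataFrame with one row per (sample, probe set), ordered by sample then
    probe set, with the four category tallies, the informative count and the
    positive/negative/insufficient_cells call.  The output is invariant to
    the row order of the input.
    """
    known = probe_sets if probe_sets is not None else DEFAULT_PROBE_SETS
    required = {"sample_id", "probe_set", "red", "green", "fusion"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"FISH table is missing columns: {sorted(missing)}")
    unknown = set(cells["probe_set"].unique()) - set(known)
    if unknown:
        raise KeyError(f"unknown probe set id(s): {sorted(unknown)}")

    rows = []
    for (sample, pset), grp in cells.groupby(["sample_id", "probe_set"], sort=True):
        signals = [
            CellSignal(int(r), int(g), int(f))
            for r, g, f in zip(grp["red"], grp["green"], grp["fusion"])
        ]
        res = call_sample(
            signals,
            min_cells=min_cells,
            min_fusion_cells=min_fusion_cells,
            sample_id=str(sample),
            probe_set=str(pset),
        )
        rows.append(
            {
                "sample_id": res.sample_id,
                "probe_set": res.probe_set,
                "n_cells_scored": res.n_cells_scored,
                **{c: res.tallies[c] for c in CATEGORIES},
                "n_informative": res.n_informative,
                "call": res.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "probe_set",
            "n_cells_scored",
            *CATEGORIES,
            "n_informative",
            "call",
        ],
    )
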