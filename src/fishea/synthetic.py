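"""Synthetic cytogenetic and expression data with known ground truth.

Every downstream stage (karyotype recurrence mining, FISH calling, the
breakpoint-window expression screen) is exercised on data from these
generators, so recovery can be scored against planted truth without any
external download.  Three generators mirror the three data modalities of a
Barrett's-carcinogenesis cell-line study:

* :func:`gen_expression_dataset` — an FPKM gene-by-sample matrix with
  i.i.d. log-normal background, a configurable fraction of entirely silent
  genes, and multiplicative effects planted inside the breakpoint windows;
* :func:`gen_fish_cells` — per-nucleus dual-color signal counts under
  normal / gain / break-without-fusion / fusion ground-truth states, with
  dropout (sectioning truncates nuclei) and spurious red-green overlap
  (juxtaposed cell layers) noise;
* :func:`gen_karyotype_set` — replicate ISCN strings in which a set of
  acquired aberrations appears with configurable penetrance.

All randomness flows from a single integer seed per call; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import DEFAULT_WINDOWS, RegionWindow
from .fish import CellSignal
from .iscn import Aberration, Karyotype, format_karyotype, parse_karyotype

__all__ = [
    "EffectSpec",
    "FishStateMix",
    "gen_expression_dataset",
    "gen_fish_cells",
    "gen_fish_table",
    "gen_karyotype_set",
    "DEFAULT_SAMPLES",
]

#: Time-course sample names of the acid+bile exposure model (weeks of exposure).
DEFAULT_SAMPLES = ("BEC0W", "BEC20W", "BEC40W", "BEC60W")

FISH_STATES = ("normal", "gain", "break_no_fusion", "fusion")

# genome lengths (Hg19, Mb-rounded) used to place background genes
_CHROM_LENGTH = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 180_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 135_000_000, "11": 135_000_000, "12": 133_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 102_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000,
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted expression effect: gene, signed fold change, window placement.

    ``true_fold_change`` uses the signed convention (+r up, -r down, |r| >= 1)
    and applies multiplicatively on the raw FPKM scale to the contrast's
    numerator sample.  ``window_id`` places the gene inside one of the
    breakpoint windows, or anywhere outside them for ``"background"``.
    """

    gene_id: str
    true_fold_change: float
    window_id: str = "background"

    def __post_init__(self) -> None:
        if abs(self.true_fold_change) < 1:
            raise ValueError("|true_fold_change| must be >= 1 (signed convention)")

    @property
    def ratio(self) -> float:
        fc = self.true_fold_change
        return fc if fc >= 0 else -1.0 / fc


@dataclass(frozen=True)
class FishStateMix:
    """Ground-truth nucleus state fractions plus the two noise probabilities.

    ``dropout_prob`` is the chance any one true signal goes unobserved (the
    nucleus is truncated by the 4-5 um section); ``spurious_overlap_prob`` is
    the chance an unrelated red/green pair is miscounted as one co-localized
    signal (overlapping cell layers).
    """

    normal: float = 1.0
    gain: float = 0.0
    break_no_fusion: float = 0.0
    fusion: float = 0.0
    dropout_prob: float = 0.0
    spurious_overlap_prob: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.normal, self.gain, self.break_no_fusion, self.fusion)
        if any(f < 0 for f in fracs):
            raise ValueError("state fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"state fractions must sum to 1, got {sum(fracs)}")
        for name in ("dropout_prob", "spurious_overlap_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.normal, self.gain, self.break_no_fusion, self.fusion)


# ---------------------------------------------------------------------------
# expression


def _place_in_window(rng: np.random.Generator, w: RegionWindow) -> tuple[int, int]:
    length = int(rng.integers(5_000, 100_000))
    span = max(w.end - w.start - length, 1)
    start = int(w.start + rng.integers(0, span))
    return start, start + length


def _place_background(
    rng: np.random.Generator, windows: Sequence[RegionWindow]
) -> tuple[str, int, int]:
    chroms = sorted(_CHROM_LENGTH, key=int)
    while True:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(5_000, 100_000))
        start = int(rng.integers(1, _CHROM_LENGTH[chrom] - length))
        end = start + length
        if not any(w.chrom == chrom and start <= w.end and end >= w.start for w in windows):
            return chrom, start, end


def gen_expression_dataset(
    n_genes: int,
    sample_names: Sequence[str] = DEFAULT_SAMPLES,
    effects: Sequence[EffectSpec] = (),
    background_sd: float = 0.2,
    seed: int = 0,
    contrast: tuple[str, str] = ("BEC40W", "BEC20W"),
    median_fpkm: float = 5.0,
    zero_fraction: float = 0.2,
    windows: Mapping[str, RegionWindow] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[EffectSpec]]:
    """Simulate an FPKM matrix, a matching Hg19 annotation, and its truth.

    Expressed genes are i.i.d. log-normal per gene and sample: ``FPKM =
    median_fpkm * exp(background_sd * z)``; ``background_sd`` is the ln-scale
    technical spread between samples (the study design has one library per
    time point, so 0.2 — roughly a 20% coefficient of variation — emulates
    technical-replicate-level noise).  A ``zero_fraction`` of background
    genes is entirely silent in all samples, exercising the x = 0 fixed
    point of the log normalization.  Each effect gene is multiplied by its
    signed fold change in the contrast's numerator sample only, so the
    expected (ln-scale) contrast equals the planted fold change, exactly so
    when ``background_sd = 0``.

    Returns ``(fpkm, annotation, truth)`` with effect genes placed inside
    their declared windows and background genes guaranteed outside every
    window.
    """
    effects = list(effects)
    if n_genes < len(effects):
        raise ValueError(f"n_genes={n_genes} < number of effects ({len(effects)})")
    ids = [e.gene_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in effects")
    if not 0.0 <= zero_fraction < 0.5:
        raise ValueError("zero_fraction must be in [0, 0.5) to keep the median positive")
    if background_sd < 0:
        raise ValueError("background_sd must be >= 0")
    win = dict(windows) if windows is not None else dict(DEFAULT_WINDOWS)
    for e in effects:
        if e.window_id != "background" and e.window_id not in win:
            raise ValueError(f"effect {e.gene_id}: unknown window {e.window_id!r}")
    sample_names = list(sample_names)
    for s in contrast:
        if s not in sample_names:
            raise ValueError(f"contrast sample {s!r} not in sample_names")

    rng = np.random.default_rng(seed)
    n_bg = n_genes - len(effects)
    gene_ids = ids + [f"BG{i:05d}" for i in range(n_bg)]

    values = median_fpkm * np.exp(
        background_sd * rng.standard_normal((n_genes, len(sample_names)))
    )
    # silent background genes: all-zero rows
    n_zero = int(round(zero_fraction * n_bg))
    if n_zero:
        silent = len(effects) + rng.choice(n_bg, size=n_zero, replace=False)
        values[np.sort(silent), :] = 0.0
    a_idx = sample_names.index(contrast[0])
    for row, e in enumerate(effects):
        if e.true_fold_change >= 0:
            values[row, a_idx] *= e.true_fold_change
        else:
            values[row, a_idx] /= -e.true_fold_change

    fpkm = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_names)

    window_list = list(win.values())
    records = []
    for e in effects:
        if e.window_id == "background":
            chrom, start, end = _place_background(rng, window_list)
        else:
            w = win[e.window_id]
            chrom = w.chrom
            start, end = _place_in_window(rng, w)
        records.append((e.gene_id, chrom, start, end))
    for gid in gene_ids[len(effects):]:
        chrom, start, end = _place_background(rng, window_list)
        records.append((gid, chrom, start, end))
    ann = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end"])
    return fpkm, ann, effects


# ---------------------------------------------------------------------------
# FISH


def _emit_state(state: str, rng: np.random.Generator, consume_parents: bool) -> tuple[int, int, int]:
    if state == "normal":
        return 2, 2, 0
    if state == "gain":
        extra = 1 + int(rng.poisson(0.3))
        if rng.integers(0, 2) == 0:
            return 2 + extra, 2, 0
        return 2, 2 + extra, 0
    if state == "break_no_fusion":
        if rng.integers(0, 2) == 0:
            return 3, 2, 0
        return 2, 3, 0
    if state == "fusion":
        if consume_parents:
            return 1, 1, 1
        return 2, 2, 1
    raise ValueError(f"unknown state {state!r}")  # pragma: no cover


def gen_fish_cells(
    n_cells: int,
    mix: FishStateMix,
    seed: int = 0,
    consume_parents: bool = True,
) -> tuple[list[CellSignal], list[str]]:
    """Simulate per-nucleus signal counts under a ground-truth state mix.

    State emissions before noise: ``normal`` (2,2,0); ``gain`` one or more
    extra signals of a random color; ``break_no_fusion`` 3 of one color, 2 of
    the other; ``fusion`` one red/green pair converted to a co-localized
    signal — by default the pair is consumed ((1,1,1): red and green mark the
    intact parent chromosomes, yellow the fusion), or kept alongside it
    ((2,2,1)) with ``consume_parents=False``.  Dropout then removes each
    signal independently, and each surviving unrelated red/green pair is
    miscounted as a fusion with the spurious-overlap probability.

    Returns the cells and the index-aligned ground-truth state labels.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    states = rng.choice(len(FISH_STATES), size=n_cells, p=mix.fractions)
    cells: list[CellSignal] = []
    truth: list[str] = []
    for si in states:
        state = FISH_STATES[si]
        red, green, fusion = _emit_state(state, rng, consume_parents)
        if mix.dropout_prob > 0:
            red = int(rng.binomial(red, 1.0 - mix.dropout_prob))
            green = int(rng.binomial(green, 1.0 - mix.dropout_prob))
            fusion = int(rng.binomial(fusion, 1.0 - mix.dropout_prob))
        if mix.spurious_overlap_prob > 0:
            k = int(rng.binomial(min(red, green), mix.spurious_overlap_prob))
            red -= k
            green -= k
            fusion += k
        cells.append(CellSignal(red, green, fusion))
        truth.append(state)
    return cells, truth


def gen_fish_table(
    design: Mapping[str, Mapping[str, tuple[int, FishStateMix]]],
    seed: int = 0,
    consume_parents: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format FISH count table for a cohort.

    ``design`` maps sample_id -> probe_set -> (n_cells, mix).  Returns the
    cell table (sample_id, probe_set, cell_index, red, green, fusion) and an
    index-aligned truth table with the ground-truth state per cell.  Each
    (sample, probe set) group gets its own child seed, so adding a group
    never perturbs the others.
    """
    root = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for sample in sorted(design):
        for pset in sorted(design[sample]):
            n_cells, mix = design[sample][pset]
            sub_seed = int(root.integers(0, 2**31 - 1))
            cells, truth = gen_fish_cells(n_cells, mix, seed=sub_seed, consume_parents=consume_parents)
            for i, (c, t) in enumerate(zip(cells, truth)):
                rows.append((sample, pset, i, c.red, c.green, c.fusion))
                truth_rows.append((sample, pset, i, t))
    cells_df = pd.DataFrame(
        rows, columns=["sample_id", "probe_set", "cell_index", "red", "green", "fusion"]
    )
    truth_df = pd.DataFrame(truth_rows, columns=["sample_id", "probe_set", "cell_index", "state"])
    return cells_df, truth_df


# ---------------------------------------------------------------------------
# karyotypes


def gen_karyotype_set(
    base: Karyotype,
    added: Sequence[Aberration],
    penetrance: float,
    n_replicates: int,
    seed: int = 0,
    exact: bool = False,
) -> list[str]:
    """Simulate replicate ISCN strings with acquired aberrations.

    Each replicate carries all ``added`` aberrations with probability
    ``penetrance`` (all-or-none per replicate, emulating a clonal event).
    With ``exact=True`` the carrier count is fixed at
    ``round(penetrance * n_replicates)`` and only the assignment of carriers
    to replicates is randomized — use this to reconstruct an observed
    "k of n replicates" pattern deterministically.  Carrier modal counts are
    adjusted by +1 per added whole-chromosome gain and -1 per loss.  Every
    returned string round-trips through the parser.
    """
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if exact:
        k = int(round(penetrance * n_replicates))
        carriers = np.zeros(n_replicates, dtype=bool)
        carriers[rng.permutation(n_replicates)[:k]] = True
    else:
        carriers = rng.random(n_replicates) < penetrance

    delta_modal = sum(1 if a.kind == "gain" else -1 if a.kind == "loss" else 0 for a in added)
    out = []
    for carrier in carriers:
        if carrier:
            k = Karyotype(
                modal_count=base.modal_count + delta_modal,
                sex_designation=base.sex_designation,
                aberrations=tuple(base.aberrations) + tuple(added),
            )
        else:
            k = base
        text = format_karyotype(k)
        parse_karyotype(text)  # every emitted string must be parseable
        out.append(text)
    return out
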