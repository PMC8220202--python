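"""End-to-end orchestration: simulate -> karyotype / FISH / expression -> report.

``run_demo`` rehearses the whole analysis on synthetic data with known ground
truth: replicate karyotypes with an acquired three-way translocation, a FISH
cohort with fusion-positive and negative samples over the three probe sets,
and an FPKM matrix with effects planted in the breakpoint windows.  The
report bundle (JSON + TSVs) records every stage's output plus recovery
metrics against the planted truth, and is byte-identical for a fixed seed.
"""

from __future__ import annotations

import shutil
import tempfile
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io as fio
from .expression import (
    DEFAULT_WINDOWS,
    RegionWindow,
    candidate_genes,
    log_normalize,
    median_adjust,
)
from .fish import screen_probe_sets
from .iscn import (
    Karyotype,
    find_recurrent,
    format_aberration,
    parse_aberration,
    parse_karyotype,
)
from .synthetic import (
    EffectSpec,
    FishStateMix,
    gen_expression_dataset,
    gen_fish_table,
    gen_karyotype_set,
)

__all__ = [
    "RunConfig",
    "DemoReport",
    "StageError",
    "run_demo",
    "validate_inputs",
    "load_windows_yaml",
]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


# ---------------------------------------------------------------------------
# configuration


class EffectConfig(BaseModel):
    gene_id: str
    true_fold_change: float
    window_id: str = "background"


class ExpressionConfig(BaseModel):
    n_genes: int = 500
    sample_names: list[str] = ["BEC0W", "BEC20W", "BEC40W", "BEC60W"]
    contrast: tuple[str, str] = ("BEC40W", "BEC20W")
    background_sd: float = 0.2
    zero_fraction: float = 0.2
    effects: list[EffectConfig] = Field(
        default_factory=lambda: [
            EffectConfig(gene_id="EFF_2P22_UP", true_fold_change=4.0, window_id="2p22"),
            EffectConfig(gene_id="EFF_2P22_DN", true_fold_change=-5.0, window_id="2p22"),
            EffectConfig(gene_id="EFF_10Q22_UP", true_fold_change=8.0, window_id="10q22"),
            EffectConfig(gene_id="EFF_16Q22_DN", true_fold_change=-3.0, window_id="16q22"),
        ]
    )
    fc_threshold: float = 2.0
    alpha: float = 0.025
    mode: Literal["shifted", "raw"] = "shifted"


class FishMixConfig(BaseModel):
    n_cells: int = 50
    normal: float = 1.0
    gain: float = 0.0
    break_no_fusion: float = 0.0
    fusion: float = 0.0
    dropout_prob: float = 0.0
    spurious_overlap_prob: float = 0.0

    def to_mix(self) -> FishStateMix:
        return FishStateMix(
            normal=self.normal,
            gain=self.gain,
            break_no_fusion=self.break_no_fusion,
            fusion=self.fusion,
            dropout_prob=self.dropout_prob,
            spurious_overlap_prob=self.spurious_overlap_prob,
        )


def _default_fish_design() -> dict[str, dict[str, FishMixConfig]]:
    # a fusion-positive tumor on every probe set vs an all-normal Barrett's sample
    positive = FishMixConfig(
        n_cells=50, normal=0.55, gain=0.15, break_no_fusion=0.10, fusion=0.20,
        dropout_prob=0.05, spurious_overlap_prob=0.002,
    )
    negative = FishMixConfig(n_cells=50, dropout_prob=0.05, spurious_overlap_prob=0.002)
    return {
        "EAC_tumor": {"set1": positive, "set2": negative.model_copy(), "set3": negative.model_copy()},
        "BE_nondysplastic": {s: negative.model_copy() for s in ("set1", "set2", "set3")},
    }


class FishConfig(BaseModel):
    design: dict[str, dict[str, FishMixConfig]] = Field(default_factory=_default_fish_design)
    min_cells: int = 25
    min_fusion_cells: int = 2


class KaryotypeConfig(BaseModel):
    base: str = "47,XY,add(4)(p16.1),add(7)(p22),i(8)(q10),+20"
    added: list[str] = ["t(2;10;16)(p22;q22;q22)", "+20"]
    penetrance: float = 4.0 / 6.0
    exact: bool = True
    n_replicates: int = 6
    resolution: Literal["exact", "major_band", "chromosomes_only"] = "major_band"
    min_count: int = 2

    @field_validator("penetrance")
    @classmethod
    def _penetrance_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        return v


class RunConfig(BaseModel):
    """Full configuration for one end-to-end demo run."""

    seed: int = 0
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)
    fish: FishConfig = Field(default_factory=FishConfig)
    karyotype: KaryotypeConfig = Field(default_factory=KaryotypeConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# report schema


class RecurrenceEntry(BaseModel):
    aberration: str
    count: int
    total_occurrences: int
    per_karyotype: list[int]


class FishCallEntry(BaseModel):
    sample_id: str
    probe_set: str
    n_cells_scored: int
    n_informative: int
    normal: int
    gain_or_break: int
    fusion_positive: int
    uninformative: int
    call: str


class CandidateEntry(BaseModel):
    window: str
    gene_id: str
    chrom: str
    start: int
    end: int
    fc: float
    log10fc: float
    p: float
    passes: bool


class TruthMetrics(BaseModel):
    karyotype_expected_carriers: int
    karyotype_observed_count: int
    fish_correct_calls: int
    fish_n_samples: int
    expression_sensitivity: float
    expression_sign_agreement: float
    expression_n_detectable: int


class DemoReport(BaseModel):
    """Schema of the structured JSON report written by :func:`run_demo`."""

    seed: int
    parameters: dict
    recurrence: list[RecurrenceEntry]
    fish_calls: list[FishCallEntry]
    candidates: list[CandidateEntry]
    truth_metrics: TruthMetrics


# ---------------------------------------------------------------------------
# run


def run_demo(config: RunConfig, out_dir: str | Path) -> DemoReport:
    """Run simulate -> all three analysis stages -> report bundle.

    Writes ``report.json`` plus TSVs (recurrence table, FISH calls, candidate
    genes) and the simulated inputs under ``out_dir``.  Output is staged in a
    temporary directory and moved into place only on success, so a failing
    stage (raised as :class:`StageError`) leaves no partial outputs.
    """
    out_dir = Path(out_dir)
    root = np.random.default_rng(config.seed)
    seeds = {name: int(root.integers(0, 2**31 - 1)) for name in ("karyotype", "fish", "expression")}
    tmp = Path(tempfile.mkdtemp(prefix=".fishea-demo-", dir=out_dir.parent if out_dir.parent.exists() else None))
    try:
        # --- karyotype stage -------------------------------------------------
        try:
            kc = config.karyotype
            base = parse_karyotype(kc.base)
            added = [parse_aberration(t) for t in kc.added]
            strings = gen_karyotype_set(
                base, added, kc.penetrance, kc.n_replicates, seed=seeds["karyotype"], exact=kc.exact
            )
            karyotypes = [parse_karyotype(s) for s in strings]
            groups = find_recurrent(karyotypes, min_count=kc.min_count, resolution=kc.resolution)
            recurrence = [
                RecurrenceEntry(
                    aberration=format_aberration(g.representative),
                    count=g.count,
                    total_occurrences=g.total_occurrences,
                    per_karyotype=list(g.per_karyotype),
                )
                for g in groups
            ]
            kar_table = pd.DataFrame(
                {
                    "replicate_id": [f"rep{i+1}" for i in range(len(strings))],
                    "condition": "simulated",
                    "karyotype": strings,
                }
            )
            fio.write_karyotype_table(kar_table, tmp / "karyotypes.tsv")
            expected_carriers = (
                int(round(kc.penetrance * kc.n_replicates)) if kc.exact
                else sum(len(k.aberrations) > len(base.aberrations) for k in karyotypes)
            )
            added_keys = {format_aberration(a) for a in added}
            observed = max(
                (g.count for g in find_recurrent(karyotypes, 1, kc.resolution)
                 if format_aberration(g.representative) in added_keys
                 and format_aberration(g.representative) not in
                 {format_aberration(a) for a in base.aberrations}),
                default=0,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("karyotype", e) from e

        # --- FISH stage ------------------------------------------------------
        try:
            fc = config.fish
            design = {
                s: {p: (m.n_cells, m.to_mix()) for p, m in psets.items()}
                for s, psets in fc.design.items()
            }
            cells, truth_cells = gen_fish_table(design, seed=seeds["fish"])
            calls = screen_probe_sets(
                cells, min_cells=fc.min_cells, min_fusion_cells=fc.min_fusion_cells
            )
            fio.write_fish_csv(cells, tmp / "fish_cells.csv")
            calls.to_csv(tmp / "fish_calls.tsv", sep="\t", index=False)
            fish_entries = [FishCallEntry(**row) for row in calls.to_dict("records")]
            # ground truth: a (sample, probe set) group is truly positive when
            # its design mix contains any fusion-state cells
            correct = 0
            for row in calls.itertuples():
                mix = fc.design[row.sample_id][row.probe_set]
                expected = "positive" if mix.fusion > 0 else "negative"
                correct += int(row.call == expected)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("fish", e) from e

        # --- expression stage ------------------------------------------------
        try:
            ec = config.expression
            effects = [EffectSpec(e.gene_id, e.true_fold_change, e.window_id) for e in ec.effects]
            fpkm, ann, truth_effects = gen_expression_dataset(
                n_genes=ec.n_genes,
                sample_names=ec.sample_names,
                effects=effects,
                background_sd=ec.background_sd,
                seed=seeds["expression"],
                contrast=tuple(ec.contrast),
                zero_fraction=ec.zero_fraction,
            )
            norm = log_normalize(fpkm)
            cand = candidate_genes(
                norm,
                ann,
                contrast=tuple(ec.contrast),
                fc_threshold=ec.fc_threshold,
                alpha=ec.alpha,
                mode=ec.mode,
            )
            fio.write_fpkm_tsv(fpkm, tmp / "fpkm.tsv")
            fio.write_annotation_bed(ann, tmp / "annotation.bed")
            cand.to_csv(tmp / "candidate_genes.tsv", sep="\t", index=False)
            fio.write_json(
                {
                    "effects": [
                        {"gene_id": e.gene_id, "true_fold_change": e.true_fold_change,
                         "window_id": e.window_id}
                        for e in truth_effects
                    ],
                    "fish_states": truth_cells.to_dict("records"),
                },
                tmp / "truth.json",
            )
            detectable = [
                e for e in truth_effects
                if e.window_id != "background" and abs(e.true_fold_change) > ec.fc_threshold
            ]
            by_gene = cand.set_index("gene_id")
            hits = [e for e in detectable if e.gene_id in by_gene.index and by_gene.loc[e.gene_id, "passes"]]
            signs_ok = [
                e for e in hits
                if np.sign(by_gene.loc[e.gene_id, "fc"]) == np.sign(e.true_fold_change)
            ]
            sensitivity = len(hits) / len(detectable) if detectable else float("nan")
            sign_agreement = len(signs_ok) / len(hits) if hits else float("nan")
            candidate_entries = [
                CandidateEntry(**{**row, "chrom": str(row["chrom"])})
                for row in cand[cand["passes"]].to_dict("records")
            ]
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("expression", e) from e

        report = DemoReport(
            seed=config.seed,
            parameters=config.model_dump(mode="json"),
            recurrence=recurrence,
            fish_calls=fish_entries,
            candidates=candidate_entries,
            truth_metrics=TruthMetrics(
                karyotype_expected_carriers=expected_carriers,
                karyotype_observed_count=observed,
                fish_correct_calls=correct,
                fish_n_samples=len(calls),
                expression_sensitivity=sensitivity,
                expression_sign_agreement=sign_agreement,
                expression_n_detectable=len(detectable),
            ),
        )
        pd.DataFrame([e.model_dump() for e in recurrence]).to_csv(
            tmp / "recurrence.tsv", sep="\t", index=False
        )
        (tmp / "report.json").write_text(report.model_dump_json(indent=2) + "\n")

        out_dir.mkdir(parents=True, exist_ok=True)
        for f in sorted(tmp.iterdir()):
            shutil.move(str(f), out_dir / f.name)
        return report
    finally:
        shutil.rmtree(tmp, ignore_errors=True)


# ---------------------------------------------------------------------------
# validation


def validate_inputs(paths: Mapping[str, str | Path]) -> list[dict]:
    """Validate input files without mutating them.

    ``paths`` maps a format name (``fpkm``, ``annotation``, ``fish``,
    ``karyotype``) to a file path.  Returns one record per file with
    ``{"path", "format", "ok", "error"}``; unreadable or malformed files are
    reported, never raised.
    """
    readers = {
        "fpkm": fio.read_fpkm_tsv,
        "annotation": fio.read_annotation,
        "fish": fio.read_fish_csv,
        "karyotype": _validate_karyotype_file,
    }
    out = []
    for fmt, path in paths.items():
        if fmt not in readers:
            out.append({"path": str(path), "format": fmt, "ok": False,
                        "error": f"unknown format {fmt!r}"})
            continue
        try:
            readers[fmt](path)
            out.append({"path": str(path), "format": fmt, "ok": True, "error": None})
        except Exception as e:  # noqa: BLE001
            out.append({"path": str(path), "format": fmt, "ok": False, "error": str(e)})
    return out


def _validate_karyotype_file(path) -> None:
    table = fio.read_karyotype_table(path)
    for i, text in enumerate(table["karyotype"]):
        try:
            parse_karyotype(text)
        except Exception as e:  # noqa: BLE001
            raise ValueError(f"row {i + 1} ({table['replicate_id'].iloc[i]}): {e}") from e


def load_windows_yaml(path) -> list[RegionWindow]:
    """Load breakpoint windows from YAML: ``windows: [{id, chrom, start, end}]``."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["windows"] if isinstance(doc, dict) else doc
    return [
        RegionWindow(id=str(e["id"]), chrom=str(e["chrom"]), start=int(e["start"]), end=int(e["end"]))
        for e in entries
    ]
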