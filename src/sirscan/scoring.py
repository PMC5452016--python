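"""Six-condition position mask, per-ORF SIR scores and positivity calls.

A genomic position is SIR-masked when, simultaneously, the Sir2, Sir3 and
Sir4 enrichments exceed their thresholds, the GFP-control enrichment stays
below its ceiling (excluding hyper-ChIPable artifacts at highly expressed
loci), H4-K16 acetylation is depleted, and the H3 signal is retained
(excluding nucleosome-depleted regions). All six comparisons are strict;
positions where any enrichment is undefined are never masked.

The SIR score of an ORF is T / length, where T counts masked positions
inside the ORF span; an ORF is SIR-positive when its score strictly
exceeds the positivity cutoff (default 0.2, i.e. more than 20% of its
sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import FACTORS, EnrichmentBundle
from .genome import GenomeAnnotation, Interval, OrfRecord, classify_orf_location


class ScoringError(ValueError):
    """Raised for invalid thresholds or inconsistent scoring inputs."""


@dataclass(frozen=True)
class MaskThresholds:
    """Enrichment thresholds of the six-condition mask (dimensionless)."""

    sir2_min: float = 1.75
    sir3_min: float = 1.5
    sir4_min: float = 2.0
    gfp_max: float = 3.0
    h4k16ac_max: float = 0.3
    h3_min: float = 0.75

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ScoringError(f"threshold {name} must be > 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class PositionMask:
    """Per-chromosome boolean vectors of SIR-masked positions."""

    data: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def to_intervals(self) -> list[Interval]:
        """Merge adjacent true positions into maximal intervals (BED export)."""
        out: list[Interval] = []
        for chrom in sorted(self.data):
            vec = self.data[chrom]
            padded = np.concatenate([[False], vec, [False]])
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for s, e in zip(edges[::2], edges[1::2]):
                out.append(Interval(chrom, int(s), int(e)))
        return out

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.to_intervals():
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\n")


# condition -> (factor, direction); "gt" means E must exceed, "lt" stay below
CONDITIONS: dict[str, tuple[str, str]] = {
    "sir2": ("sir2_min", "gt"),
    "sir3": ("sir3_min", "gt"),
    "sir4": ("sir4_min", "gt"),
    "gfp": ("gfp_max", "lt"),
    "h4k16ac": ("h4k16ac_max", "lt"),
    "h3": ("h3_min", "gt"),
}


def sir_position_mask(
    bundle: EnrichmentBundle,
    thresholds: MaskThresholds | None = None,
    conditions: Sequence[str] = tuple(FACTORS),
) -> PositionMask:
    """Positions passing every listed threshold condition on defined values.

    ``conditions`` defaults to all six factors; passing a subset ablates the
    remaining conditions (used for testing what each control excludes).
    Undefined positions of the *listed* factors are always false.
    """
    thresholds = thresholds or MaskThresholds()
    unknown = [c for c in conditions if c not in CONDITIONS]
    if unknown:
        raise ScoringError(f"unknown mask condition(s): {', '.join(unknown)}")
    if not conditions:
        raise ScoringError("at least one mask condition required")
    tdict = thresholds.as_dict()
    data: dict[str, np.ndarray] = {}
    for chrom, n in bundle.chrom_lengths.items():
        mask = np.ones(n, dtype=bool)
        for factor in conditions:
            attr, direction = CONDITIONS[factor]
            track = bundle[factor]
            values = track.values[chrom]
            cutoff = tdict[attr]
            with np.errstate(invalid="ignore"):
                passed = values > cutoff if direction == "gt" else values < cutoff
            mask &= passed & track.defined[chrom]
        data[chrom] = mask
    return PositionMask(
        data,
        provenance={"thresholds": tdict, "conditions": list(conditions)},
    )


def orf_sir_score(orf: OrfRecord, mask: PositionMask) -> tuple[int, float]:
    """(T, score): masked-position count within the ORF and its fraction."""
    if orf.chromosome not in mask.data:
        raise ScoringError(f"ORF {orf.id!r}: chromosome {orf.chromosome!r} not in mask")
    vec = mask.data[orf.chromosome]
    if orf.end > len(vec):
        raise ScoringError(f"ORF {orf.id!r}: extends beyond mask on {orf.chromosome!r}")
    t = int(np.count_nonzero(vec[orf.start:orf.end]))
    return t, t / orf.length


def score_orfs(
    annotation: GenomeAnnotation,
    mask: PositionMask,
    telomere_window_bp: int = 20_000,
    hm_window_bp: int = 10_000,
) -> pd.DataFrame:
    """SIR score table: one row per ORF with T, score and location class.

    Positions overlapping two ORFs count for both; ORFs are scored
    independently.
    """
    rows = []
    for orf in annotation.orfs:
        t, score = orf_sir_score(orf, mask)
        location = classify_orf_location(
            orf, annotation, telomere_window_bp=telomere_window_bp, hm_window_bp=hm_window_bp
        )
        rows.append(
            {
                "id": orf.id,
                "chrom": orf.chromosome,
                "start": orf.start,
                "end": orf.end,
                "strand": orf.strand,
                "length": orf.length,
                "T": t,
                "score": score,
                "location": location.value,
            }
        )
    columns = ["id", "chrom", "start", "end", "strand", "length", "T", "score", "location"]
    return pd.DataFrame(rows, columns=columns)


def classify_sir_positive(table: pd.DataFrame, cutoff: float = 0.2) -> pd.DataFrame:
    """Add the ``positive`` column: score strictly greater than ``cutoff``."""
    if not (0 < cutoff < 1):
        raise ScoringError(f"positivity cutoff must be in (0, 1), got {cutoff}")
    out = table.copy()
    out["positive"] = out["score"] > cutoff
    return out


def positivity_counts(table: pd.DataFrame) -> dict[str, int]:
    """Overall and per-location-class counts of SIR-positive ORFs."""
    if "positive" not in table.columns:
        raise ScoringError("table has no 'positive' column; run classify_sir_positive")
    pos = table[table["positive"]]
    counts = {
        "n_orfs": int(len(table)),
        "n_positive": int(len(pos)),
        "n_positive_subtelomeric": int((pos["location"] == "subtelomeric").sum()),
        "n_positive_hm_proximal": int((pos["location"] == "hm_proximal").sum()),
        "n_positive_interior": int((pos["location"] == "interior").sum()),
    }
    counts["n_positive_subtel_or_hm"] = (
        counts["n_positive_subtelomeric"] + counts["n_positive_hm_proximal"]
    )
    return counts


def expression_quartile_crosstab(
    table: pd.DataFrame, expression: pd.Series | dict[str, float]
) -> pd.DataFrame:
    """Cross-tabulate SIR positivity against gene-expression quartiles.

    Quartile boundaries sit at the 25th/50th/75th percentiles of the
    expression values of ORFs present in both inputs; bins are
    lower-closed with boundary ties assigned to the lower quartile.
    ORFs lacking an expression value are reported in a separate row.
    """
    if "positive" not in table.columns:
        raise ScoringError("table has no 'positive' column; run classify_sir_positive")
    expr = pd.Series(expression, dtype=float)
    matched = table[table["id"].isin(expr.index)]
    if matched.empty:
        raise ScoringError("no ORF ids overlap between score table and expression values")
    values = expr.loc[matched["id"]].to_numpy()
    boundaries = np.percentile(values, [25, 50, 75])
    # index of first boundary >= value: ties land in the lower quartile
    quartile = np.searchsorted(boundaries, values, side="left")
    labels = np.array(["I", "II", "III", "IV"])[quartile]
    rows = []
    positive = matched["positive"].to_numpy()
    for q in ["I", "II", "III", "IV"]:
        in_q = labels == q
        rows.append(
            {
                "quartile": q,
                "n_orfs": int(in_q.sum()),
                "n_positive": int((in_q & positive).sum()),
                "n_negative": int((in_q & ~positive).sum()),
            }
        )
    missing = table[~table["id"].isin(expr.index)]
    rows.append(
        {
            "quartile": "no_expression",
            "n_orfs": int(len(missing)),
            "n_positive": int(missing["positive"].sum()),
            "n_negative": int((~missing["positive"]).sum()),
        }
    )
    return pd.DataFrame(rows, columns=["quartile", "n_orfs", "n_positive", "n_negative"])


def threshold_sensitivity_sweep(
    bundle: EnrichmentBundle,
    annotation: GenomeAnnotation,
    thresholds: MaskThresholds | None = None,
    cutoff: float = 0.2,
    perturbation: float = 0.10,
    telomere_window_bp: int = 20_000,
    hm_window_bp: int = 10_000,
) -> pd.DataFrame:
    """SIR-positive counts under +/- ``perturbation`` of each threshold.

    One row per (threshold, direction) perturbation plus the baseline;
    reports how stable the positive-ORF count is to small threshold moves.
    """
    thresholds = thresholds or MaskThresholds()
    base = thresholds.as_dict()

    def count(th: MaskThresholds) -> int:
        mask = sir_position_mask(bundle, th)
        table = classify_sir_positive(
            score_orfs(annotation, mask, telomere_window_bp, hm_window_bp), cutoff
        )
        return int(table["positive"].sum())

    rows = [{"threshold": "baseline", "direction": "0", "value": np.nan,
             "n_positive": count(thresholds)}]
    for name in base:
        for sign, tag in ((1 + perturbation, "+"), (1 - perturbation, "-")):
            perturbed = dict(base)
            perturbed[name] = base[name] * sign
            rows.append(
                {
                    "threshold": name,
                    "direction": tag,
                    "value": perturbed[name],
                    "n_positive": count(MaskThresholds(**perturbed)),
                }
            )
    return pd.DataFrame(rows, columns=["threshold", "direction", "value", "n_positive"])


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["score"] = out["score"].map(lambda s: f"{s:.4g}")
    out.to_csv(path, sep="\t", index=False)
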