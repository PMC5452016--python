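"""Distance from ORF centers to the nearest ORC binding site.

ORC sites are half-open intervals (merged before any computation). The
distance of an ORF is measured from its center position to the nearest
edge of the nearest site: 0 when the center lies inside a site, otherwise
the gap in bp between the center and the closest covered position.
Distances are intra-chromosomal; ORFs on chromosomes without any site get
a missing distance and are excluded from summaries (the exclusion count
is reported).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, Interval, OrfRecord, merge_intervals, orf_center


class ProximityError(ValueError):
    """Raised for inconsistent distance-analysis inputs."""


def point_to_site_distance(center: int, site: Interval, reference: str = "edge") -> int:
    """bp between a point and one site; 0 inside (edge mode)."""
    if reference == "edge":
        if site.start <= center < site.end:
            return 0
        if center < site.start:
            return site.start - center
        return center - (site.end - 1)
    if reference == "midpoint":
        return abs(center - (site.start + site.end) // 2)
    raise ProximityError(f"unknown site reference {reference!r}")


def nearest_orc_distance(
    orf: OrfRecord,
    sites: Sequence[Interval],
    reference: str = "edge",
) -> tuple[int, Interval]:
    """(distance, site) for the nearest ORC site on the ORF's chromosome.

    ``sites`` must be merged, sorted intervals on one chromosome. Distance
    ties are broken toward the leftmost site (the distance itself is
    unambiguous).
    """
    on_chrom = [s for s in sites if s.chromosome == orf.chromosome]
    if not on_chrom:
        raise ProximityError(f"no ORC sites on chromosome {orf.chromosome!r}")
    center = orf_center(orf)
    best_d, best_site = None, None
    for site in on_chrom:
        d = point_to_site_distance(center, site, reference)
        if best_d is None or d < best_d:
            best_d, best_site = d, site
    return best_d, best_site


def distance_table(
    annotation: GenomeAnnotation,
    score_table: pd.DataFrame | None = None,
    reference: str = "edge",
) -> pd.DataFrame:
    """Per-ORF nearest-ORC distance, with SIR calls carried through.

    ORFs on site-free chromosomes get NaN distance; the caller can count
    them via the NaN rows. When ``score_table`` is given, its ``score``,
    ``positive`` and ``location`` columns are joined on ORF id.
    """
    sites = merge_intervals(annotation.orc_sites)
    by_chrom: dict[str, list[Interval]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s)
    rows = []
    for orf in annotation.orfs:
        center = orf_center(orf)
        row: dict = {
            "id": orf.id,
            "chrom": orf.chromosome,
            "center": center,
            "distance": np.nan,
            "site_start": pd.NA,
            "site_end": pd.NA,
        }
        chrom_sites = by_chrom.get(orf.chromosome)
        if chrom_sites:
            d, site = nearest_orc_distance(orf, chrom_sites, reference)
            row.update(distance=float(d), site_start=site.start, site_end=site.end)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", "chrom", "center", "distance", "site_start", "site_end"])
    if score_table is not None:
        extra = [c for c in ("score", "positive", "location") if c in score_table.columns]
        df = df.merge(score_table[["id", *extra]], on="id", how="left")
    return df


def distance_summary(distances: pd.DataFrame, within_bp: int = 750) -> dict:
    """Headline distance statistics.

    Reports the median distance over all ORFs, the median over SIR-positive
    interior ORFs (neither subtelomeric nor HM-proximal), and the fraction
    of that set closer than ``within_bp`` to a site. Medians of even counts
    are the mean of the two central values. Empty sets yield None, not 0.
    """
    defined = distances[distances["distance"].notna()]
    if defined.empty:
        raise ProximityError("no ORF has a defined nearest-ORC distance")
    summary: dict = {
        "n_orfs": int(len(distances)),
        "n_with_distance": int(len(defined)),
        "n_excluded_no_site_on_chromosome": int(len(distances) - len(defined)),
        "median_distance_all_orfs": float(np.median(defined["distance"])),
        "within_bp": int(within_bp),
    }
    if {"positive", "location"}.issubset(defined.columns):
        green = defined[(defined["positive"] == True) & (defined["location"] == "interior")]  # noqa: E712
        summary["n_sir_positive_interior"] = int(len(green))
        if len(green):
            d = green["distance"].to_numpy()
            summary["median_distance_sir_positive_interior"] = float(np.median(d))
            summary["fraction_within"] = float(np.mean(d < within_bp))
        else:
            summary["median_distance_sir_positive_interior"] = None
            summary["fraction_within"] = None
    return summary


def write_distance_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
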