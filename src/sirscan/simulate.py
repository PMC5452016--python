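"""Seeded synthetic genomes, ChIP-seq coverage tracks and ground truth.

The generator plants three region classes on a background genome and
emulates the track logic the six-condition mask discriminates:

* true SIR domains — Sir2/3/4 IP enriched, H4-K16ac depleted, H3 and the
  GFP control flat;
* hyper-ChIPable decoys — identical to true domains in the Sir and
  H4-K16ac channels but with elevated GFP-control signal, the artifact
  signature of highly expressed loci that the E_GFP ceiling excludes;
* nucleosome-depleted decoys — identical to true domains except for a
  depleted H3 signal, the signature the E_H3 floor excludes.

Coverage is independent per-position Poisson: input tracks at the
background depth, IP tracks at background depth times the region- and
factor-specific fold. ORC sites are planted at exact center-to-site-edge
offsets from designated true-domain ORFs, plus uniform background sites
kept far enough away that the planted offset stays the nearest site.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import FACTORS, CoverageTrack, write_bedgraph
from .genome import (
    Chromosome,
    GenomeAnnotation,
    Interval,
    OrfRecord,
    write_bed,
    write_gff3,
)

SIR_DOMAIN = "sir_domain"
HYPERCHIP = "hyperchip_decoy"
NUCDEPLETED = "nucdepleted_decoy"
BACKGROUND = "background"
LABELS = (SIR_DOMAIN, HYPERCHIP, NUCDEPLETED, BACKGROUND)


class SimulationError(ValueError):
    """Raised for invalid parameters or infeasible region placement."""


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the default synthetic scenario.

    Folds are multiplicative enrichments of IP over input inside planted
    regions; they sit well beyond the mask thresholds (Sir folds 4 vs
    minima 1.5-2; H4-K16ac 0.1 vs ceiling 0.3; decoy GFP 4 vs ceiling 3;
    decoy H3 0.3 vs floor 0.75) so that recovery is limited by sampling
    noise only.
    """

    n_chromosomes: int = 4
    chromosome_length_bp: int = 150_000
    n_orfs: int = 200
    orf_length_range: tuple[int, int] = (500, 1500)
    background_depth: float = 50.0
    n_true_domains: int = 10
    sir2_fold: float = 4.0
    sir3_fold: float = 4.0
    sir4_fold: float = 4.0
    h4k16ac_fold: float = 0.1
    h3_fold: float = 1.0
    gfp_fold: float = 1.0
    n_hyperchip_decoys: int = 5
    hyperchip_gfp_fold: float = 4.0
    n_nucdepleted_decoys: int = 5
    nucdepleted_h3_fold: float = 0.3
    domain_margin_bp: int = 200
    orc_offsets: tuple[int, ...] = (0, 100, 750, 5000)
    n_background_orc_sites: int = 20
    orc_site_width: int = 33
    n_hm_loci: int = 2
    hm_locus_length_bp: int = 3_000
    clear_of_ends_bp: int = 25_000
    clear_of_hm_bp: int = 12_000
    seed: int = 1

    def __post_init__(self) -> None:
        folds = {
            "sir2_fold": self.sir2_fold,
            "sir3_fold": self.sir3_fold,
            "sir4_fold": self.sir4_fold,
            "h4k16ac_fold": self.h4k16ac_fold,
            "h3_fold": self.h3_fold,
            "gfp_fold": self.gfp_fold,
            "hyperchip_gfp_fold": self.hyperchip_gfp_fold,
            "nucdepleted_h3_fold": self.nucdepleted_h3_fold,
        }
        for name, value in folds.items():
            if not value > 0:
                raise SimulationError(f"{name} must be > 0, got {value}")
        if self.background_depth < 1:
            raise SimulationError("background_depth must be >= 1")
        lo, hi = self.orf_length_range
        if not (1 <= lo <= hi):
            raise SimulationError("invalid orf_length_range")
        n_labeled = self.n_true_domains + self.n_hyperchip_decoys + self.n_nucdepleted_decoys
        if n_labeled > self.n_orfs:
            raise SimulationError("more planted regions than ORFs")
        if len(self.orc_offsets) > self.n_true_domains:
            raise SimulationError("more ORC offsets than true domains to attach them to")
        if any(d < 0 for d in self.orc_offsets):
            raise SimulationError("ORC offsets must be >= 0")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orf_length_range"] = list(d["orf_length_range"])
        d["orc_offsets"] = list(d["orc_offsets"])
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: labels, regions, planted offsets."""

    orf_labels: dict[str, str]
    regions: list[tuple[str, Interval]]
    orc_offset_orfs: dict[str, int]
    params: SimulationParams

    def orfs_with_label(self, label: str) -> list[str]:
        return [oid for oid, lab in self.orf_labels.items() if lab == label]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "orf_id": oid,
                "label": lab,
                "planted_orc_offset": self.orc_offset_orfs.get(oid, pd.NA),
            }
            for oid, lab in self.orf_labels.items()
        ]
        return pd.DataFrame(rows, columns=["orf_id", "label", "planted_orc_offset"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def _overlaps_any(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def simulate_genome(params: SimulationParams) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Place chromosomes, HM loci, ORFs, planted regions and ORC sites.

    Deterministic given ``params.seed``. Planted regions are the labeled
    ORFs extended by ``domain_margin_bp`` on each side; they never overlap
    each other, any other ORF, or the HM-locus neighbourhoods, and sit
    clear of chromosome ends so that planted ORFs classify as interior
    under the default location windows.
    """
    rng = np.random.default_rng([params.seed, 1])
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    n = params.chromosome_length_bp
    chromosomes = [Chromosome(name, n) for name in chrom_names]

    # HM loci in the central region, away from chromosome ends
    hm_loci: list[Interval] = []
    hm_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for _ in range(params.n_hm_loci):
        for _attempt in range(1000):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            start = int(rng.integers(params.clear_of_ends_bp,
                                     n - params.clear_of_ends_bp - params.hm_locus_length_bp))
            end = start + params.hm_locus_length_bp
            if not _overlaps_any(start - params.clear_of_hm_bp, end + params.clear_of_hm_bp,
                                 hm_by_chrom[chrom]):
                hm_loci.append(Interval(chrom, start, end))
                hm_by_chrom[chrom].append((start, end))
                break
        else:
            raise SimulationError("could not place HM loci; shrink them or grow the genome")

    # non-overlapping ORFs, uniform over the genome
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    orfs: list[OrfRecord] = []
    lo, hi = params.orf_length_range
    for i in range(params.n_orfs):
        for _attempt in range(5000):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            length = int(rng.integers(lo, hi + 1))
            if length >= n:
                continue
            start = int(rng.integers(0, n - length))
            end = start + length
            if _overlaps_any(start, end, occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            orfs.append(OrfRecord(f"ORF{i + 1:04d}", chrom, start, end, strand))
            occupied[chrom].append((start, end))
            break
        else:
            raise SimulationError(
                "could not place all ORFs without overlap; reduce n_orfs or grow the genome"
            )

    # pick labeled ORFs whose extended regions are mutually clear
    margin = params.domain_margin_bp
    wanted = (
        [SIR_DOMAIN] * params.n_true_domains
        + [HYPERCHIP] * params.n_hyperchip_decoys
        + [NUCDEPLETED] * params.n_nucdepleted_decoys
    )
    order = rng.permutation(len(orfs))
    regions: list[tuple[str, Interval]] = []
    region_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    orf_labels = {o.id: BACKGROUND for o in orfs}
    labeled: list[OrfRecord] = []
    # domain centers must be far enough apart that each planted ORC site
    # stays the nearest site for its own ORF
    min_center_sep = 2 * max(params.orc_offsets, default=0) + params.orc_site_width + 1000
    domain_centers: dict[str, list[int]] = {c: [] for c in chrom_names}
    queue = list(order)
    for label in wanted:
        placed = False
        while queue:
            orf = orfs[queue.pop(0)]
            rstart, rend = orf.start - margin, orf.end + margin
            if rstart < params.clear_of_ends_bp or rend > n - params.clear_of_ends_bp:
                continue
            others = [(o.start, o.end) for o in orfs
                      if o.chromosome == orf.chromosome and o.id != orf.id]
            if _overlaps_any(rstart, rend, others):
                continue
            if _overlaps_any(rstart, rend, region_spans[orf.chromosome]):
                continue
            hm_pad = [(s - params.clear_of_hm_bp, e + params.clear_of_hm_bp)
                      for s, e in hm_by_chrom[orf.chromosome]]
            if _overlaps_any(rstart, rend, hm_pad):
                continue
            if label == SIR_DOMAIN and any(
                abs(orf.center - c) < min_center_sep for c in domain_centers[orf.chromosome]
            ):
                continue
            regions.append((label, Interval(orf.chromosome, rstart, rend)))
            region_spans[orf.chromosome].append((rstart, rend))
            if label == SIR_DOMAIN:
                domain_centers[orf.chromosome].append(orf.center)
            orf_labels[orf.id] = label
            labeled.append(orf)
            placed = True
            break
        if not placed:
            raise SimulationError(
                "could not place all planted regions; reduce region counts, "
                "margins, or ORF density"
            )

    # ORC sites: planted at exact offsets from the first true-domain ORFs
    domain_orfs = [o for o in labeled if orf_labels[o.id] == SIR_DOMAIN]
    width = params.orc_site_width
    orc_sites: list[Interval] = []
    orc_offset_orfs: dict[str, int] = {}
    for orf, offset in zip(domain_orfs, params.orc_offsets):
        center = orf.center
        if offset == 0:
            start = center - width // 2
        else:
            start = center + offset  # site to the right; nearest edge is its start
        orc_sites.append(Interval(orf.chromosome, start, start + width))
        orc_offset_orfs[orf.id] = int(offset)

    # background sites: at least one per chromosome, all kept far from
    # designated centers so the planted offset remains the nearest site
    exclusion = max(params.orc_offsets, default=0) + width + 1000
    centers = {c: [o.center for o in domain_orfs if o.chromosome == c] for c in chrom_names}

    def far_enough(chrom: str, start: int) -> bool:
        return all(abs(start - c) > exclusion and abs(start + width - c) > exclusion
                   for c in centers[chrom])

    n_background = max(params.n_background_orc_sites, params.n_chromosomes)
    targets = chrom_names + [chrom_names[int(rng.integers(len(chrom_names)))]
                             for _ in range(n_background - params.n_chromosomes)]
    for chrom in targets:
        for _attempt in range(1000):
            start = int(rng.integers(0, n - width))
            if far_enough(chrom, start):
                orc_sites.append(Interval(chrom, start, start + width))
                break
        else:
            raise SimulationError("could not place background ORC sites")

    annotation = GenomeAnnotation(chromosomes, orfs, hm_loci=hm_loci, orc_sites=orc_sites)
    truth = SyntheticTruth(orf_labels, regions, orc_offset_orfs, params)
    return annotation, truth


# per-label fold of each factor's IP over its input inside planted regions
def _fold_table(params: SimulationParams) -> dict[str, dict[str, float]]:
    domain = {
        "sir2": params.sir2_fold,
        "sir3": params.sir3_fold,
        "sir4": params.sir4_fold,
        "gfp": params.gfp_fold,
        "h4k16ac": params.h4k16ac_fold,
        "h3": params.h3_fold,
    }
    hyperchip = dict(domain, gfp=params.hyperchip_gfp_fold)
    nucdepleted = dict(domain, h3=params.nucdepleted_h3_fold)
    return {SIR_DOMAIN: domain, HYPERCHIP: hyperchip, NUCDEPLETED: nucdepleted}


def simulate_tracks(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    params: SimulationParams,
) -> dict[str, CoverageTrack]:
    """Twelve coverage tracks (six IP + six matched inputs), Poisson noise.

    Keys are ``"{factor}_ip"`` and ``"{factor}_input"``. Inputs are flat
    Poisson(background_depth); IPs are Poisson(background_depth * fold)
    with the fold profile of the planted region the position lies in.
    """
    rng = np.random.default_rng([params.seed, 2])
    folds = _fold_table(params)
    lengths = annotation.chrom_lengths
    lam_by_factor: dict[str, dict[str, np.ndarray]] = {
        f: {c: np.full(n, params.background_depth) for c, n in lengths.items()}
        for f in FACTORS
    }
    for label, region in truth.regions:
        for factor in FACTORS:
            lam = lam_by_factor[factor][region.chromosome]
            lam[region.start:region.end] = params.background_depth * folds[label][factor]
    tracks: dict[str, CoverageTrack] = {}
    for factor in FACTORS:
        ip_data = {c: rng.poisson(lam_by_factor[factor][c]).astype(float) for c in sorted(lengths)}
        in_data = {c: rng.poisson(params.background_depth, lengths[c]).astype(float)
                   for c in sorted(lengths)}
        tracks[f"{factor}_ip"] = CoverageTrack(f"{factor}_ip", ip_data)
        tracks[f"{factor}_input"] = CoverageTrack(f"{factor}_input", in_data)
    return tracks


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    params: SimulationParams,
) -> pd.Series:
    """Per-ORF expression levels (arbitrary units, log-normal background).

    Planted SIR-domain and hyper-ChIPable ORFs are highly expressed —
    strictly above every background value — mirroring the observation
    that SIR-enriched loci sit among the most highly expressed genes.
    """
    rng = np.random.default_rng([params.seed, 3])
    values = {}
    background = rng.lognormal(mean=3.0, sigma=1.0, size=len(annotation.orfs))
    top = float(background.max())
    for orf, base in zip(annotation.orfs, background):
        label = truth.orf_labels[orf.id]
        if label in (SIR_DOMAIN, HYPERCHIP):
            values[orf.id] = top * (1.5 + rng.random())
        else:
            values[orf.id] = float(base)
    return pd.Series(values, name="expression")


def truth_evaluation(score_table: pd.DataFrame, truth: SyntheticTruth) -> dict:
    """Recovery of planted labels by the SIR-positive classification.

    Sensitivity is the fraction of true-domain ORFs called positive;
    false positives are broken down by decoy/background class. Exact
    counts, no smoothing.
    """
    if "positive" not in score_table.columns:
        raise ValueError("score table has no 'positive' column; run classify_sir_positive")
    table_ids = set(score_table["id"])
    truth_ids = set(truth.orf_labels)
    if table_ids != truth_ids:
        raise ValueError(
            f"ORF id mismatch between score table and truth "
            f"({len(table_ids - truth_ids)} only in table, "
            f"{len(truth_ids - table_ids)} only in truth)"
        )
    positive = dict(zip(score_table["id"], score_table["positive"]))
    counts = {label: {"n": 0, "n_positive": 0} for label in LABELS}
    for oid, label in truth.orf_labels.items():
        counts[label]["n"] += 1
        if positive[oid]:
            counts[label]["n_positive"] += 1
    n_dom = counts[SIR_DOMAIN]["n"]
    return {
        "n_sir_domain": n_dom,
        "n_true_positive": counts[SIR_DOMAIN]["n_positive"],
        "sensitivity": counts[SIR_DOMAIN]["n_positive"] / n_dom if n_dom else None,
        "false_positive_hyperchip": counts[HYPERCHIP]["n_positive"],
        "false_positive_nucdepleted": counts[NUCDEPLETED]["n_positive"],
        "false_positive_background": counts[BACKGROUND]["n_positive"],
        "n_hyperchip": counts[HYPERCHIP]["n"],
        "n_nucdepleted": counts[NUCDEPLETED]["n"],
        "n_background": counts[BACKGROUND]["n"],
    }


def write_inputs(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    tracks: dict[str, CoverageTrack],
    outdir: str | Path,
) -> dict[str, str]:
    """Write standard pipeline inputs: bedGraphs, GFF3, BEDs, truth, params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    lengths = annotation.chrom_lengths
    lengths_path = outdir / "chrom_lengths.tsv"
    with open(lengths_path, "w") as fh:
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")
    paths["chrom_lengths"] = str(lengths_path)
    gff_path = outdir / "orfs.gff3"
    write_gff3(annotation.orfs, gff_path)
    paths["annotation"] = str(gff_path)
    orc_path = outdir / "orc_sites.bed"
    write_bed(annotation.orc_sites, orc_path)
    paths["orc_sites"] = str(orc_path)
    hm_path = outdir / "hm_loci.bed"
    write_bed(annotation.hm_loci, hm_path)
    paths["hm_loci"] = str(hm_path)
    for name, track in tracks.items():
        p = outdir / f"{name}.bedgraph"
        write_bedgraph(track.data, p)
        paths[name] = str(p)
    truth_path = outdir / "truth.tsv"
    truth.write(truth_path)
    paths["truth"] = str(truth_path)
    params_path = outdir / "params.json"
    with open(params_path, "w") as fh:
        json.dump(truth.params.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["params"] = str(params_path)
    return paths
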