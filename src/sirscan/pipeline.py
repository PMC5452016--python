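"""End-to-end orchestration: config, staged execution, report bundle.

A pipeline run consumes a YAML config naming the six IP/input coverage
pairs and the annotation files, and emits the SIR-domain report bundle:
mask BED, SIR score table, ORC distance table, threshold-sensitivity
sweep, summary JSON and a provenance JSON echoing every tunable plus the
per-sample normalization medians. Reruns on identical inputs are
byte-identical; no timestamps enter any output.

The monolithic :func:`run_pipeline` keeps intermediates in memory. The
stage functions (``stage_normalize`` ... ``stage_report``) read and write
intermediates on disk with floats serialized at full precision, so a
staged run produces bitwise the same bundle as the monolithic one.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (
    FACTORS,
    CoverageTrack,
    EnrichmentTrack,
    build_bundle,
    enrichment,
    median_normalize,
    read_coverage,
    write_bedgraph,
)
from .genome import GenomeAnnotation, read_annotation, read_chrom_lengths
from .orc import distance_summary, distance_table, write_distance_table
from .scoring import (
    MaskThresholds,
    PositionMask,
    classify_sir_positive,
    expression_quartile_crosstab,
    positivity_counts,
    score_orfs,
    sir_position_mask,
    threshold_sensitivity_sweep,
    write_score_table,
)
from .simulate import SyntheticTruth, truth_evaluation


class ConfigError(ValueError):
    """Raised when the pipeline config is malformed or incomplete."""


DEFAULT_PARAMS: dict = {
    "thresholds": MaskThresholds().as_dict(),
    "positivity_cutoff": 0.2,
    "telomere_window_bp": 20_000,
    "hm_window_bp": 10_000,
    "within_bp": 750,
    "normalization_policy": "all_positions",
    "sweep_perturbation": 0.10,
    "orc_site_reference": "edge",
    "coverage_format": "bedgraph",
}

BUNDLE_FILES = (
    "mask.bed",
    "sir_scores.tsv",
    "distances.tsv",
    "sweep.tsv",
    "expression_crosstab.tsv",
    "summary.json",
)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return validate_config(config)


def validate_config(config: dict) -> dict:
    inputs = config.get("inputs")
    if not isinstance(inputs, dict):
        raise ConfigError("config needs an 'inputs' mapping")
    for key in ("chrom_lengths", "annotation", "orc_sites"):
        if key not in inputs:
            raise ConfigError(f"config inputs missing {key!r}")
    samples = inputs.get("samples")
    if not isinstance(samples, dict):
        raise ConfigError("config inputs needs a 'samples' mapping (factor -> ip/input)")
    missing = [f for f in FACTORS if f not in samples]
    if missing:
        raise ConfigError(f"sample manifest missing factor(s): {', '.join(missing)}")
    paths = []
    for factor in FACTORS:
        pair = samples[factor]
        if not isinstance(pair, dict) or "ip" not in pair or "input" not in pair:
            raise ConfigError(f"sample {factor!r} needs 'ip' and 'input' paths")
        paths += [pair["ip"], pair["input"]]
    if len(set(paths)) != len(paths):
        raise ConfigError("sample manifest paths must be distinct")
    params = dict(DEFAULT_PARAMS)
    thresholds = dict(DEFAULT_PARAMS["thresholds"])
    user_params = config.get("params") or {}
    if not isinstance(user_params, dict):
        raise ConfigError("'params' must be a mapping")
    unknown = set(user_params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ConfigError(f"unknown param(s): {', '.join(sorted(unknown))}")
    thresholds.update(user_params.get("thresholds") or {})
    params.update(user_params)
    params["thresholds"] = thresholds
    try:
        MaskThresholds(**thresholds)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid thresholds: {exc}") from exc
    if not (0 < params["positivity_cutoff"] < 1):
        raise ConfigError("positivity_cutoff must be in (0, 1)")
    return {"inputs": inputs, "params": params}


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canonical).hexdigest()


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_annotation(config: dict) -> GenomeAnnotation:
    inputs = config["inputs"]
    lengths = read_chrom_lengths(inputs["chrom_lengths"])
    return read_annotation(
        inputs["annotation"],
        lengths,
        hm_bed=inputs.get("hm_loci"),
        orc_bed=inputs["orc_sites"],
    )


def load_and_normalize(config: dict) -> dict[str, CoverageTrack]:
    """Read all twelve coverage files and median-normalize each."""
    inputs = config["inputs"]
    lengths = read_chrom_lengths(inputs["chrom_lengths"])
    policy = config["params"]["normalization_policy"]
    fmt = config["params"]["coverage_format"]
    tracks = {}
    for factor in FACTORS:
        for role in ("ip", "input"):
            name = f"{factor}_{role}"
            raw = read_coverage(
                inputs["samples"][factor][role], lengths, format=fmt, sample_id=name
            )
            tracks[name] = median_normalize(raw, policy)
    return tracks


def build_enrichment(tracks: dict[str, CoverageTrack]) -> dict[str, EnrichmentTrack]:
    return {
        factor: enrichment(tracks[f"{factor}_ip"], tracks[f"{factor}_input"], factor)
        for factor in FACTORS
    }


def _medians_of(tracks: dict[str, CoverageTrack]) -> dict:
    return {
        name: {
            "median": track.provenance["median"],
            "policy": track.provenance["normalization_policy"],
        }
        for name, track in sorted(tracks.items())
    }


# ---------------------------------------------------------------------------
# monolithic run


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute normalize -> enrich -> mask -> score -> classify -> orc-dist
    -> sweep -> report in memory and write the bundle into ``outdir``.

    Partial outputs are removed if any stage fails. Returns the summary
    dict that is also written as ``summary.json``.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(config: dict, outdir: Path, written: list[Path]) -> dict:
    params = config["params"]
    annotation = load_annotation(config)
    tracks = load_and_normalize(config)
    bundle = build_bundle(build_enrichment(tracks).values())
    thresholds = MaskThresholds(**params["thresholds"])

    mask = sir_position_mask(bundle, thresholds)
    written.append(outdir / "mask.bed")
    mask.write_bed(outdir / "mask.bed")

    table = score_orfs(
        annotation, mask,
        telomere_window_bp=params["telomere_window_bp"],
        hm_window_bp=params["hm_window_bp"],
    )
    table = classify_sir_positive(table, params["positivity_cutoff"])
    written.append(outdir / "sir_scores.tsv")
    write_score_table(table, outdir / "sir_scores.tsv")

    distances = distance_table(annotation, table, reference=params["orc_site_reference"])
    written.append(outdir / "distances.tsv")
    write_distance_table(distances, outdir / "distances.tsv")

    sweep = threshold_sensitivity_sweep(
        bundle, annotation, thresholds,
        cutoff=params["positivity_cutoff"],
        perturbation=params["sweep_perturbation"],
        telomere_window_bp=params["telomere_window_bp"],
        hm_window_bp=params["hm_window_bp"],
    )
    written.append(outdir / "sweep.tsv")
    sweep.to_csv(outdir / "sweep.tsv", sep="\t", index=False, float_format="%.6g")

    summary = _write_report(config, outdir, table, distances, sweep,
                            _medians_of(tracks), written)
    return summary


# ---------------------------------------------------------------------------
# staged execution (CLI subcommands); intermediates on disk


def stage_normalize(config: dict, outdir: str | Path) -> None:
    """Write median-normalized bedGraphs + medians.json under normalized/."""
    outdir = Path(outdir)
    norm_dir = outdir / "normalized"
    norm_dir.mkdir(parents=True, exist_ok=True)
    tracks = load_and_normalize(config)
    for name, track in tracks.items():
        write_bedgraph(track.data, norm_dir / f"{name}.bedgraph")
    with open(norm_dir / "medians.json", "w") as fh:
        json.dump(_medians_of(tracks), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_normalized(config: dict, outdir: Path) -> dict[str, CoverageTrack]:
    lengths = read_chrom_lengths(config["inputs"]["chrom_lengths"])
    norm_dir = Path(outdir) / "normalized"
    with open(norm_dir / "medians.json") as fh:
        medians = json.load(fh)
    tracks = {}
    for factor in FACTORS:
        for role in ("ip", "input"):
            name = f"{factor}_{role}"
            track = read_coverage(norm_dir / f"{name}.bedgraph", lengths, sample_id=name)
            track.normalized = True
            track.provenance.update(
                median=medians[name]["median"],
                normalization_policy=medians[name]["policy"],
            )
            tracks[name] = track
    return tracks


def stage_enrich(config: dict, outdir: str | Path) -> None:
    """Write per-factor enrichment bedGraphs (NaN at undefined positions)."""
    outdir = Path(outdir)
    enrich_dir = outdir / "enrichment"
    enrich_dir.mkdir(parents=True, exist_ok=True)
    tracks = _read_normalized(config, outdir)
    for factor, track in build_enrichment(tracks).items():
        write_bedgraph(track.values, enrich_dir / f"{factor}.bedgraph")


def read_enrichment_dir(config: dict, outdir: str | Path):
    lengths = read_chrom_lengths(config["inputs"]["chrom_lengths"])
    enrich_dir = Path(outdir) / "enrichment"
    tracks = []
    for factor in FACTORS:
        cov = read_coverage(
            enrich_dir / f"{factor}.bedgraph", lengths, sample_id=factor, allow_nan=True
        )
        defined = {c: ~np.isnan(v) for c, v in cov.data.items()}
        tracks.append(EnrichmentTrack(factor, cov.data, defined))
    return build_bundle(tracks)


def stage_mask(config: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    bundle = read_enrichment_dir(config, outdir)
    thresholds = MaskThresholds(**config["params"]["thresholds"])
    mask = sir_position_mask(bundle, thresholds)
    mask.write_bed(outdir / "mask.bed")


def _read_mask(config: dict, outdir: Path) -> PositionMask:
    lengths = read_chrom_lengths(config["inputs"]["chrom_lengths"])
    data = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    with open(outdir / "mask.bed") as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end = line.split()[:3]
            data[chrom][int(start):int(end)] = True
    return PositionMask(data)


def stage_score(config: dict, outdir: str | Path) -> None:
    """Per-ORF T and location from mask.bed -> scores_raw.tsv."""
    outdir = Path(outdir)
    annotation = load_annotation(config)
    mask = _read_mask(config, outdir)
    params = config["params"]
    table = score_orfs(
        annotation, mask,
        telomere_window_bp=params["telomere_window_bp"],
        hm_window_bp=params["hm_window_bp"],
    )
    table.drop(columns=["score"]).to_csv(outdir / "scores_raw.tsv", sep="\t", index=False)


def stage_classify(config: dict, outdir: str | Path) -> None:
    """scores_raw.tsv -> sir_scores.tsv with score and positivity call."""
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "scores_raw.tsv", sep="\t")
    table["score"] = table["T"] / table["length"]
    table = table[["id", "chrom", "start", "end", "strand", "length", "T", "score", "location"]]
    table = classify_sir_positive(table, config["params"]["positivity_cutoff"])
    write_score_table(table, outdir / "sir_scores.tsv")


def _parse_bool(column: pd.Series) -> pd.Series:
    if column.dtype == bool:
        return column
    return column.astype(str).map({"True": True, "False": False})


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Re-read sir_scores.tsv with full-precision scores reconstructed."""
    table = pd.read_csv(path, sep="\t")
    table["score"] = table["T"] / table["length"]
    table["positive"] = _parse_bool(table["positive"])
    return table


def stage_orc_dist(config: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    annotation = load_annotation(config)
    table = read_score_table(outdir / "sir_scores.tsv")
    distances = distance_table(
        annotation, table, reference=config["params"]["orc_site_reference"]
    )
    write_distance_table(distances, outdir / "distances.tsv")


def stage_sweep(config: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    bundle = read_enrichment_dir(config, outdir)
    annotation = load_annotation(config)
    params = config["params"]
    sweep = threshold_sensitivity_sweep(
        bundle, annotation, MaskThresholds(**params["thresholds"]),
        cutoff=params["positivity_cutoff"],
        perturbation=params["sweep_perturbation"],
        telomere_window_bp=params["telomere_window_bp"],
        hm_window_bp=params["hm_window_bp"],
    )
    sweep.to_csv(outdir / "sweep.tsv", sep="\t", index=False, float_format="%.6g")


def stage_report(config: dict, outdir: str | Path) -> dict:
    """Assemble summary.json, crosstab and provenance.json from stage files."""
    outdir = Path(outdir)
    table = read_score_table(outdir / "sir_scores.tsv")
    distances = pd.read_csv(outdir / "distances.tsv", sep="\t", na_values=["NA"])
    if "positive" in distances.columns:
        distances["positive"] = _parse_bool(distances["positive"])
    sweep = pd.read_csv(outdir / "sweep.tsv", sep="\t")
    with open(outdir / "normalized" / "medians.json") as fh:
        medians = json.load(fh)
    return _write_report(config, outdir, table, distances, sweep, medians, [])


# ---------------------------------------------------------------------------
# shared report/provenance builder


def _write_report(
    config: dict,
    outdir: Path,
    table: pd.DataFrame,
    distances: pd.DataFrame,
    sweep: pd.DataFrame,
    medians: dict,
    written: list[Path],
) -> dict:
    params = config["params"]
    inputs = config["inputs"]
    summary: dict = {
        "positivity": positivity_counts(table),
        "distance": distance_summary(distances, within_bp=params["within_bp"]),
        "threshold_sweep": {
            "perturbation": params["sweep_perturbation"],
            "n_positive_baseline": int(sweep.loc[0, "n_positive"]),
            "n_positive_min": int(sweep["n_positive"].min()),
            "n_positive_max": int(sweep["n_positive"].max()),
        },
    }

    if inputs.get("expression"):
        expr = pd.read_csv(inputs["expression"], sep="\t", index_col=0).iloc[:, 0]
        crosstab = expression_quartile_crosstab(table, expr)
        written.append(outdir / "expression_crosstab.tsv")
        crosstab.to_csv(outdir / "expression_crosstab.tsv", sep="\t", index=False)
        summary["expression_crosstab"] = crosstab.to_dict(orient="records")

    if inputs.get("truth"):
        truth_frame = pd.read_csv(inputs["truth"], sep="\t", na_values=["NA"])
        labels = dict(zip(truth_frame["orf_id"], truth_frame["label"]))
        truth = SyntheticTruth(labels, [], {}, params=None)
        summary["truth_evaluation"] = truth_evaluation(table, truth)

    written.append(outdir / "summary.json")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    provenance = {
        "tool": "sirscan",
        "version": __version__,
        "config": config,
        "config_sha256": config_hash(config),
        "normalization": medians,
        "input_sha256": {
            key: _sha256_file(Path(path)) for key, path in _iter_input_paths(inputs)
        },
        "output_sha256": {
            name: _sha256_file(outdir / name)
            for name in BUNDLE_FILES
            if (outdir / name).exists()
        },
    }
    written.append(outdir / "provenance.json")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary


def _iter_input_paths(inputs: dict):
    for key in ("chrom_lengths", "annotation", "orc_sites", "hm_loci", "expression", "truth"):
        if inputs.get(key):
            yield key, inputs[key]
    for factor in FACTORS:
        for role in ("ip", "input"):
            yield f"{factor}_{role}", inputs["samples"][factor][role]


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
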