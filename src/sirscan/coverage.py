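"""Per-position coverage tracks, median normalization and IP/input enrichment.

A :class:`CoverageTrack` holds one dense vector of non-negative depth per
chromosome, at base-pair resolution. Tracks are normalized by dividing every
position by the genome-wide median depth of the sample, after which the
per-position enrichment E of an immunoprecipitated (IP) sample over its
matched input is the plain ratio of the two normalized tracks. Positions
where the normalized input is zero have no defined ratio; they are flagged
undefined rather than patched with a pseudocount, and simply fail any
downstream threshold mask.

Tracks are expected to originate from MAPQ-filtered alignments (MAPQ >= 10);
this is an ingestion requirement recorded in provenance, not re-applied here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

FACTORS = ("sir2", "sir3", "sir4", "gfp", "h4k16ac", "h3")


class CoverageError(ValueError):
    """Raised for malformed coverage input or inconsistent track operations."""


@dataclass
class CoverageTrack:
    """Dense per-position depth for one sample over a genome."""

    sample_id: str
    data: dict[str, np.ndarray]
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            if vec.ndim != 1:
                raise CoverageError(f"{self.sample_id}/{chrom}: vector must be 1-D")
            if np.any(vec < 0):
                raise CoverageError(f"{self.sample_id}/{chrom}: negative depth")
            self.data[chrom] = vec

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])

    def genome_median(self, policy: str = "all_positions") -> float:
        values = self.concatenated()
        if policy == "nonzero_only":
            values = values[values > 0]
            if values.size == 0:
                raise CoverageError(f"{self.sample_id}: no nonzero positions")
        elif policy != "all_positions":
            raise CoverageError(f"unknown normalization policy {policy!r}")
        return float(np.median(values))


@dataclass
class EnrichmentTrack:
    """Per-position enrichment E = IP/input for one factor.

    ``values`` holds NaN wherever ``defined`` is False (input coverage 0).
    """

    factor: str
    values: dict[str, np.ndarray]
    defined: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values) != set(self.defined):
            raise CoverageError(f"{self.factor}: values/defined chromosome mismatch")
        for chrom in self.values:
            v = np.asarray(self.values[chrom], dtype=float)
            d = np.asarray(self.defined[chrom], dtype=bool)
            if len(v) != len(d):
                raise CoverageError(f"{self.factor}/{chrom}: length mismatch")
            if np.any(v[d] < 0):
                raise CoverageError(f"{self.factor}/{chrom}: negative enrichment")
            self.values[chrom] = v
            self.defined[chrom] = d

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}


@dataclass
class EnrichmentBundle:
    """The six enrichment tracks the position mask needs, on one genome."""

    tracks: dict[str, EnrichmentTrack]

    def __post_init__(self) -> None:
        missing = [f for f in FACTORS if f not in self.tracks]
        if missing:
            raise CoverageError(f"missing enrichment track(s): {', '.join(missing)}")
        ref = self.tracks[FACTORS[0]].chrom_lengths
        for factor in FACTORS:
            if self.tracks[factor].chrom_lengths != ref:
                raise CoverageError(f"track {factor!r}: chromosome set/length mismatch")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.tracks[FACTORS[0]].chrom_lengths

    def __getitem__(self, factor: str) -> EnrichmentTrack:
        return self.tracks[factor]


def read_coverage(
    source: str | Path | io.TextIOBase,
    chrom_lengths: dict[str, int],
    format: str = "bedgraph",
    sample_id: str = "sample",
    allow_nan: bool = False,
) -> CoverageTrack:
    """Read a bedGraph or fixed-step wiggle file into dense vectors.

    Positions absent from the file get depth 0. Overlapping bedGraph
    intervals are rejected (depth would be ambiguous), as are records
    beyond chromosome bounds or with negative depth.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_coverage(fh, chrom_lengths, format, sample_id, allow_nan)
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    if format == "bedgraph":
        _read_bedgraph(source, chrom_lengths, data, covered, allow_nan)
    elif format == "wiggle":
        _read_fixedstep_wiggle(source, chrom_lengths, data, covered, allow_nan)
    else:
        raise CoverageError(f"unknown coverage format {format!r}")
    track = CoverageTrack(sample_id, data, normalized=False)
    if allow_nan:
        track.provenance["nan_positions_allowed"] = True
    return track


def _parse_value(text: str, lineno: int, allow_nan: bool) -> float:
    value = float(text)
    if np.isnan(value):
        if not allow_nan:
            raise CoverageError(f"line {lineno}: NaN depth not allowed")
        return value
    if value < 0:
        raise CoverageError(f"line {lineno}: negative depth {value}")
    return value


def _read_bedgraph(fh, chrom_lengths, data, covered, allow_nan) -> None:
    import pandas as pd

    body = io.StringIO(
        "".join(
            line for line in fh
            if line.strip() and not line.startswith(("#", "track", "browser"))
        )
    )
    body.seek(0, io.SEEK_END)
    if body.tell() == 0:
        return
    body.seek(0)
    try:
        df = pd.read_csv(
            body, sep=r"\s+", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise CoverageError(f"malformed bedGraph: {exc}") from exc
    if df[["start", "end", "value"]].isna().any().any() and not allow_nan:
        bad = df[df.isna().any(axis=1)].iloc[0]
        raise CoverageError(f"malformed or NaN bedGraph record near {bad.tolist()}")
    for chrom, grp in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in chrom_lengths:
            raise CoverageError(f"unknown chromosome {chrom!r} in bedGraph")
        n = chrom_lengths[chrom]
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        values = grp["value"].to_numpy()
        if (starts < 0).any() or (starts >= ends).any() or (ends > n).any():
            i = int(np.flatnonzero((starts < 0) | (starts >= ends) | (ends > n))[0])
            raise CoverageError(
                f"interval {chrom}:{starts[i]}-{ends[i]} outside "
                f"chromosome bounds [0, {n})"
            )
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            i = int(np.flatnonzero(starts[1:] < ends[:-1])[0]) + 1
            raise CoverageError(
                f"overlapping interval {chrom}:{starts[i]}-{ends[i]} (ambiguous depth)"
            )
        finite = values[~np.isnan(values)]
        if (finite < 0).any():
            raise CoverageError(f"negative depth on {chrom}")
        if np.isnan(values).any() and not allow_nan:
            raise CoverageError(f"NaN depth on {chrom} not allowed")
        lens = ends - starts
        idx = np.repeat(ends - np.cumsum(lens), lens) + np.arange(lens.sum())
        data[chrom][idx] = np.repeat(values, lens)
        covered[chrom][idx] = True


def _read_fixedstep_wiggle(fh, chrom_lengths, data, covered, allow_nan) -> None:
    chrom, pos, step, span = None, None, None, 1
    for lineno, line in enumerate(fh, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in line.split()[1:])
            chrom = fields["chrom"]
            if chrom not in chrom_lengths:
                raise CoverageError(f"line {lineno}: unknown chromosome {chrom!r}")
            pos = int(fields["start"]) - 1  # wiggle is 1-based
            step = int(fields.get("step", 1))
            span = int(fields.get("span", 1))
            continue
        if chrom is None:
            raise CoverageError(f"line {lineno}: data before fixedStep header")
        end = pos + span
        if pos < 0 or end > chrom_lengths[chrom]:
            raise CoverageError(
                f"line {lineno}: position {chrom}:{pos}-{end} outside chromosome bounds"
            )
        if covered[chrom][pos:end].any():
            raise CoverageError(f"line {lineno}: overlapping wiggle span at {chrom}:{pos}")
        data[chrom][pos:end] = _parse_value(line, lineno, allow_nan)
        covered[chrom][pos:end] = True
        pos += step


def write_bedgraph(
    data: dict[str, np.ndarray], path: str | Path, precision: int = 17
) -> None:
    """Write dense vectors as a minimal run-length-merged bedGraph.

    Zero-depth runs are written too, so a read/write cycle is lossless;
    NaN runs are written as literal ``nan`` (enrichment tracks only).
    """
    import pandas as pd

    frames = []
    for chrom in sorted(data):
        vec = np.asarray(data[chrom], dtype=float)
        if vec.size == 0:
            continue
        # run boundaries where the value changes (NaN == NaN for this purpose)
        same = (vec[1:] == vec[:-1]) | (np.isnan(vec[1:]) & np.isnan(vec[:-1]))
        breaks = np.flatnonzero(~same) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(vec)]])
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": vec[starts]})
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "value"]
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format=f"%.{precision}g")


def median_normalize(track: CoverageTrack, policy: str = "all_positions") -> CoverageTrack:
    """Divide every position by the genome-wide median depth of the sample.

    With ``policy='all_positions'`` the median is taken over every reference
    position, zeros included — the domain of a per-base ``genomeCoverageBed -d``
    style track. ``'nonzero_only'`` restricts to covered positions, for
    sparse data whose all-position median would be zero.
    """
    if track.normalized:
        raise CoverageError(f"{track.sample_id}: track already normalized")
    median = track.genome_median(policy)
    if median == 0:
        raise CoverageError(
            f"{track.sample_id}: genome-wide median is 0 under policy "
            "'all_positions'; use policy 'nonzero_only' or deeper data"
        )
    data = {c: v / median for c, v in track.data.items()}
    provenance = dict(track.provenance)
    provenance.update({"median": median, "normalization_policy": policy})
    return CoverageTrack(track.sample_id, data, normalized=True, provenance=provenance)


def enrichment(ip: CoverageTrack, input_: CoverageTrack, factor: str) -> EnrichmentTrack:
    """Per-position E = normalized IP / normalized input for one factor.

    Positions with zero input coverage are flagged undefined (value NaN);
    no pseudocount is applied.
    """
    if not ip.normalized or not input_.normalized:
        raise CoverageError(f"{factor}: both tracks must be median-normalized first")
    if ip.chrom_lengths != input_.chrom_lengths:
        raise CoverageError(f"{factor}: IP and input chromosome sets/lengths differ")
    values: dict[str, np.ndarray] = {}
    defined: dict[str, np.ndarray] = {}
    for chrom, ip_vec in ip.data.items():
        in_vec = input_.data[chrom]
        ok = in_vec > 0
        e = np.full(len(ip_vec), np.nan)
        np.divide(ip_vec, in_vec, out=e, where=ok)
        values[chrom] = e
        defined[chrom] = ok
    provenance = {
        "ip_sample": ip.sample_id,
        "input_sample": input_.sample_id,
        "ip_median": ip.provenance.get("median"),
        "input_median": input_.provenance.get("median"),
    }
    return EnrichmentTrack(factor, values, defined, provenance=provenance)


def build_bundle(tracks: Iterable[EnrichmentTrack]) -> EnrichmentBundle:
    return EnrichmentBundle({t.factor: t for t in tracks})
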