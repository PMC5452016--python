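import numpy as np
import pytest

from sirscan import (
    Chromosome,
    EnrichmentTrack,
    GenomeAnnotation,
    Interval,
    OrfRecord,
    SimulationParams,
    build_bundle,
)
from sirscan.coverage import FACTORS


def make_bundle(e_by_factor, chrom="chrI"):
    """EnrichmentBundle from per-factor scalars or vectors (NaN = undefined)."""
    raw = {
        f: np.atleast_1d(np.asarray(e_by_factor[f], dtype=float)) for f in FACTORS
    }
    n = max(len(v) for v in raw.values())
    arrays = {f: (np.full(n, v[0]) if len(v) == 1 else v) for f, v in raw.items()}
    tracks = [
        EnrichmentTrack(f, {chrom: arrays[f]}, {chrom: ~np.isnan(arrays[f])})
        for f in FACTORS
    ]
    return build_bundle(tracks)


def passing_values(**overrides):
    """Per-factor enrichments that satisfy all six mask conditions."""
    values = {"sir2": 2.5, "sir3": 2.5, "sir4": 2.5, "gfp": 1.0, "h4k16ac": 0.1, "h3": 1.0}
    values.update(overrides)
    return values


def single_orf_annotation(chrom="chrI", length=1000, orf_start=0, orf_end=None,
                          orc_sites=(), hm_loci=()):
    orf_end = orf_end if orf_end is not None else length
    return GenomeAnnotation(
        chromosomes=[Chromosome(chrom, length)],
        orfs=[OrfRecord("ORF1", chrom, orf_start, orf_end, "+")],
        hm_loci=[Interval(chrom, s, e) for s, e in hm_loci],
        orc_sites=[Interval(chrom, s, e) for s, e in orc_sites],
    )


@pytest.fixture
def small_params():
    """A reduced simulation scenario for fast pipeline-level tests."""
    return SimulationParams(
        n_chromosomes=2,
        chromosome_length_bp=40_000,
        n_orfs=40,
        orf_length_range=(400, 900),
        n_true_domains=4,
        n_hyperchip_decoys=2,
        n_nucdepleted_decoys=2,
        orc_offsets=(0, 100),
        n_background_orc_sites=4,
        n_hm_loci=1,
        hm_locus_length_bp=1_000,
        clear_of_ends_bp=6_000,
        clear_of_hm_bp=3_000,
        seed=11,
    )
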