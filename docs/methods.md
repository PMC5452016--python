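# Methods

## Model and assumptions

`sirscan` treats SIR-domain detection as a per-position decision problem on
six enrichment tracks. The underlying picture: where the SIR complex is
genuinely bound, Sir2/Sir3/Sir4 ChIP signal rises together, Sir2's
deacetylase activity depletes H4-K16 acetylation, and nucleosomes remain in
place (H3 retained). Two artifact modes mimic parts of this signature:
highly expressed loci immunoprecipitate promiscuously (elevated signal even
in a GFP mock ChIP), and nucleosome-free regions lose H4-K16ac signal
trivially (together with H3). The six-condition mask encodes exactly this
logic; it is a deterministic threshold rule with no significance model or
smoothing, so every call is reproducible arithmetic on the input tracks.

The per-ORF SIR score is the fraction of the ORF's genomic span (annotated
start to end, no intron handling — yeast ORFs are overwhelmingly
intronless) that passes the mask. Positivity requires a score strictly
greater than 0.2. All mask inequalities are strict; enrichment exactly at a
threshold does not pass. These sharp semantics are asserted by an
exhaustive boundary grid in the test suite.

## Coordinates and formats

Internally everything is 0-based half-open. GFF3 (1-based inclusive) is
converted on read, BED is taken as is; chromosome lengths come from a
`.fai` or two-column TSV. Coverage is dense per-base, read from 4-column
bedGraph or fixed-step wiggle; positions absent from the file are depth 0,
and overlapping records are a fatal error because depth would be ambiguous.
Coverage is expected to originate from MAPQ ≥ 10-filtered alignments; this
is an ingestion contract recorded in provenance, not re-applied.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| `sir2_min, sir3_min, sir4_min` | 1.75, 1.5, 2 | enrichment ratio | minimum SIR-factor enrichment |
| `gfp_max` | 3 | enrichment ratio | hyper-ChIPable artifact ceiling |
| `h4k16ac_max` | 0.3 | enrichment ratio | deacetylation requirement |
| `h3_min` | 0.75 | enrichment ratio | nucleosome-retention floor |
| `positivity_cutoff` | 0.2 | score fraction | strict; score = 0.2 is negative |
| `telomere_window_bp` | 20 000 | bp | ORF span within this of a chromosome end ⇒ subtelomeric |
| `hm_window_bp` | 10 000 | bp | span within this of an HM locus ⇒ HM-proximal |
| `within_bp` | 750 | bp | near-ORC fraction threshold in the distance summary |
| `normalization_policy` | `all_positions` | — | median over every reference position |

The threshold sextet and the 0.2 cutoff are empirical working points; the
`sweep` stage reports how the positive count moves under ±10 % perturbation
of each threshold so users can check stability on their own data. The two
location windows are a genuinely open design choice — no standard
definition of "subtelomeric" or "HM-proximal" exists at base-pair precision
— so they are configuration with defaults in line with common yeast
subtelomere usage; subtelomeric takes precedence over HM-proximal (HML/HMR
themselves sit near chromosome ends), making the three-way partition
deterministic.

## Normalization and undefined ratios

The genome-wide median is computed over **all** reference positions by
default, zeros included, matching the domain of per-base coverage output
(`genomeCoverageBed -d` style); `nonzero_only` is available for sparse data
whose all-position median would be zero (a fatal error with advice
otherwise). Enrichment is a plain ratio with no pseudocount: where the
normalized input is zero the ratio is undefined, flagged as such, and the
position simply fails the mask. This is deliberately conservative —
pseudocounts would invent enrichment values precisely where the data are
weakest.

Two exact invariants follow and are asserted in tests: the median of a
normalized track is 1 (division by a positive scalar is order-preserving;
with integer depths the central values are tied in practice, making the
equality exact in floating point), and normalization is invariant to
scaling all raw depths by a constant, bitwise (the rounded quotient of
`k·a / k·m` equals that of `a / m` when `k·a` and `k·m` are exact).

## ORC distance

ORC binding sites are intervals; overlapping sites are merged before any
computation (merging provably never changes a minimum edge distance). The
per-ORF distance is measured from the ORF center, `floor((start+end)/2)`,
to the nearest edge of the nearest site on the same chromosome, 0 inside a
site; a center-to-site-midpoint variant is available as configuration for
sensitivity checks. Distances are intra-chromosomal only: ORFs on a
chromosome without sites get a missing distance and are excluded from
summaries, with the exclusion count reported rather than silently dropped.
Medians of even counts are the mean of the two central values.

## Synthetic data: what it emulates, and what it does not

The generator plants non-overlapping regions — each an ORF extended by a
200 bp margin — of three classes on a flat background, and draws coverage
as independent per-position Poisson counts: inputs at the background depth
(default 50×), IPs at depth × fold with per-class, per-factor folds.
Defaults: 4 chromosomes × 150 kb, 200 ORFs of 500–1500 bp, 10 true domains
(Sir folds 4, H4-K16ac fold 0.1, H3 and GFP folds 1), 5 hyper-ChIPable
decoys and 5 nucleosome-depleted decoys. Each decoy class deviates from the
true-domain profile in exactly one channel (GFP fold 4, or H3 fold 0.3):
this isolates each control condition, so ablating the GFP condition admits
precisely the hyper-ChIPable decoys and ablating the H3 condition precisely
the nucleosome-depleted ones — the filter logic itself is what the decoys
test. ORC sites (33 bp, the scale of an ARS consensus region) are planted
at exact center-to-edge offsets {0, 100, 750, 5000} bp from designated
true-domain ORFs, with background sites kept far enough away that the
planted offset remains the nearest site; domain placement enforces the
separation this requires. A log-normal expression table marks planted
domains and hyper-ChIPable decoys as highly expressed, mirroring the
observation that SIR-enriched loci sit among the most expressed genes.

What the simulation does **not** model: autocorrelated coverage from
fragment pileup, mappability gaps, copy-number variation, GC bias, or
partial/graded enrichment at domain borders. Passing the recovery tests
therefore demonstrates that the decision logic is implemented correctly
and discriminates the planted signatures at realistic depth — not that the
thresholds are optimal for any particular real dataset, where boundary
positions and correlated noise will blur the mask at domain edges.

All randomness flows from one integer seed (streams for genome, tracks and
expression are derived from it), and identical parameters plus seed
reproduce every file byte-identically.

## Numerical choices

- Ratios and scores are double precision throughout; report tables round
  scores to 4 significant figures only at serialization, and positivity is
  always decided on the full-precision value (stage files carry integer
  `T` and `length`, from which the score is reconstructed exactly).
- Intermediate bedGraphs written by the stage subcommands serialize floats
  with 17 significant digits and are parsed with a correctly-rounded float
  parser, so staged execution is bitwise identical to the monolithic run;
  undefined enrichment positions are serialized as literal `nan`.
- Mask BED export merges adjacent true positions into maximal intervals;
  scoring uses per-position counts, so merging is presentation-only.
- Outputs contain no timestamps; `provenance.json` carries the config
  echo, its SHA-256, per-sample normalization medians and input/output
  checksums, which is what makes byte-identical reruns checkable.

## Test problem sizes

Unit and property tests run on genomes of a few kb; the brute-force oracle
comparison uses 100 random genomes of 2–10 kb with positionwise-exact
agreement required for the mask, the per-ORF counts and the nearest-site
distances. Recovery tests run the full default scenario (600 kb genome)
across five seeds; pipeline-level determinism and stage-composition tests
use a reduced 2 × 40 kb scenario. These sizes keep the whole suite fast
while exercising every code path at the default depth and folds.

## Known limitations

- The mask is per-position and unsmoothed; single-position dropouts inside
  a real domain (sampling noise at low depth) reduce the score slightly
  rather than being bridged.
- Scores attach to annotated ORF spans only; intergenic SIR domains appear
  in `mask.bed` but receive no score.
- The expression cross-tabulation assigns quartiles by ranking the
  supplied values with lower-closed bins (ties to the lower quartile);
  different upstream expression pipelines will shift boundary genes.
- No between-sample normalization beyond the per-sample median is
  attempted; strongly different signal-to-noise between IPs changes what
  a shared threshold means.
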