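# Methods

## The labile-bond mining procedure

A disulfide bond is treated as one *unique bond* per (accession, canonical
position pair): the bond between Cys50 and Cys111 of a protein is the same
bond no matter how many crystal forms it appears in. The miner proceeds in
two passes over a corpus of legacy-PDB files.

**Screening.** A structure enters the corpus only if its REMARK 2
resolution is known and ≤ 2.5 Å, none of its heteroatom codes is on the
reducing-agent blocklist (default `DTT, DTU, DTV, BME, TCE`; configurable —
the principle is that a crystal grown in reductant cannot witness a bond's
absence), and at least one chain maps to a known accession. Exclusion
reasons (`resolution_gt_2.5`, `no_resolution`, `reducing_agent`,
`unmapped`) are recorded per structure.

**Harvesting.** Disulfides are read from SSBOND header records; an optional
geometric mode additionally picks up SG–SG pairs under 2.5 Å lacking an
SSBOND line (off by default, since header records are the declared
ground truth of deposited X-ray structures). Endpoints are translated to
canonical positions via the chain mapping; bonds joining two different
accessions are logged separately and never enter the per-protein universe,
and dangling SSBONDs (endpoints without coordinates) are logged and
skipped. Each harvested bond is measured (below) and passed through the
S–S length filter: *d* within ±10% of the 2.038 Å equilibrium length
(inclusive bounds 1.8342–2.2418 Å, with a 1 nÅ guard against coordinate
rounding). A bond outside the window keeps its value as *presence*
evidence (`present_filtered_length`) but is excluded from all geometry and
strain cohorts — the filter exists to keep poorly defined bonds out of the
statistics, not to deny that the bond was modelled.

**Absence validation.** For every known bond of an accession, every mapped
chain lacking that bond is classified: `excluded_truncated` if a position
falls outside the span of the construct, `excluded_mutated` if the aligned
residue is not cysteine, `excluded_unresolved` if the residue is cysteine
but its SG (or the whole residue, as an interior gap) is unmodelled, and
`missing` — valid evidence of lability — only when both cysteines are
present, un-mutated and fully resolved. Precedence when the two positions
disagree is truncated > mutated > unresolved, which can only ever
*suppress* lability evidence, never fabricate it.

**Aggregation.** A unique bond is **labile** iff it has at least one
present-type and at least one valid-missing observation. One structure can
supply both (homomeric copies in one crystal); such bonds carry a
`same_file_lability` flag for scrutiny. The representative geometry comes
from the present observation with the best (lowest) resolution, ties broken
lexicographically by (pdb_id, chain) so output is deterministic; length-
filtered observations are used only when nothing passed the filter. A
user-supplied pre-culled chain list (the output of an external
homology-culling service) restricts reference-cohort membership; culling is
not re-implemented.

## Geometry

Torsions use the standard signed convention of the structural-biology
toolchains (the one that makes an α-helix φ ≈ −57°); results lie in
(−180°, 180°]. The five χ torsions, the two Cβ–Sγ–Sγ′ bending angles and
the S–S distance are measured directly from coordinates; only N, CA, CB
and SG are required per cysteine, so missing backbone O/C atoms degrade
nothing but the B-factor average (which then averages the atoms present
and records a deficit count).

The dihedral strain energy uses torsional force constants of
8.37/8.37 (χ1, χ1′), 4.18/4.18 (χ2, χ2′) and 14.64 + 2.51 (two- and
threefold terms in χ3) kJ·mol⁻¹. The constants are switchable via the
`constants` argument of `dse`. Two numerical notes: the function is
invariant under side swap and under ±360° shifts, with range exactly
[0, 84.5] kJ·mol⁻¹; and because the χ3 potential is the *sum* of a two-
and a threefold term, its stationary minimum sits ~5–7° off |χ3| = 90°
(value ≈ 2.08 rather than the 2.51 obtained at exactly 90°) — tests treat
the 90° value as the anchor and the off-grid shift as expected.

## Configuration taxonomy

Handedness follows the sign of χ3; shape follows how the χ2 and χ2′ signs
relate to χ3 (both agree → spiral, both oppose → staple, one of each →
hook); the prefix records the χ1/χ1′ signs. Since the two cysteines have no
intrinsic order, names must be invariant under side swap, which collapses
the 32 sign vectors to exactly 20 classes. For hooks the mixed-χ1 patterns
form two genuinely distinct classes; the prefix is ordered by the side
whose χ2 sign agrees with χ3, so `-/+RHhook` and `+/-RHhook` are different
configurations and each name is swap-invariant. A χ angle of exactly 0° or
±180° has no sign; it is assigned `−` and the bond carries a boundary flag
so it can be dropped from configuration tallies (it never is from strain
statistics).

## Sequence mapping

Chains are assigned accessions by a local TSV table, and residue-level maps
are built by global alignment (match +1, mismatch −1, gap open −5, gap
extend −1, free terminal gaps) of the *observed* ATOM-record sequence to
the canonical FASTA sequence — observed, not SEQRES, so unresolved residues
naturally read as "not observed" and terminal truncations appear as free
end gaps. Aligned columns below 30% identity raise an "implausible
mapping" error rather than propagate nonsense positions. A SIFTS-style
per-residue TSV bypasses alignment entirely when available.

## Cohort statistics

Pearson χ² (marginal-product expecteds, upper-tail p), Welch *t*
(Satterthwaite df; pooled Student *t* by flag), paired *t* and Pearson *r*
(p via the t transform) are computed from their closed forms, with scipy
supplying only the distribution tails; an independent statistics library
verifies them in the test suite. All tests are two-sided and p values are
raw — no multiple-testing correction, since the output is a descriptive
report, not a screen. Frequency tables span all 20 configuration bins and
the six unordered secondary-structure pairs; bins empty in *both* cohorts
are dropped before the χ² test (a zero marginal makes the expected count
zero, which is an error by contract). Histograms use relative frequency
over fixed ranges — DSE 0–60 kJ·mol⁻¹, *d* 1.96–2.14 Å, mean α 95–120° —
chosen to cover the realistic span of each metric.

## The synthetic-fixture generator

The generator is the package's ground-truth instrument, not a convenience:
it *inverts* the pipeline. Cystine coordinates are built by sequential
internal-coordinate (NeRF) construction along N–Cα–Cβ–Sγ–Sγ′–Cβ′–Cα′–N′
with standard stereochemistry (N–Cα 1.458, Cα–Cβ 1.530, Cβ–Sγ 1.810 Å;
N–Cα–Cβ 110.5°, Cα–Cβ–Sγ 114.0°; S–S 2.038 Å and Cβ–Sγ–Sγ′ 104.0° by
default), so the measured internal coordinates equal the targets to
machine precision — the round-trip tolerance of 1e−6° is conservative.
Backbone C/O are completed at idealised geometry; fixtures are chemically
plausible but not energy-minimised, which is sufficient because only the
measured internal coordinates carry information.

Ensembles plant, per structure and per bond, one of five states — present
(with exact target geometry), reduced (intact cysteines, no bond),
truncated, mutated or unresolved — plus structure-level decoys (resolution
2.6 Å, a DTT heteroatom, a missing resolution record, a chain absent from
the mapping table). The default corpus cycles ten scenarios over the
proteins (four structures each) so that every observation status and every
exclusion reason occurs. Random χ targets are rotamer-like (side-chain
torsions near the ±60°/180° wells with 12° jitter, χ3 near its relaxed
±90° minimum), giving strain energies in the realistic low-teens range;
the strain-effect cohorts bias labile bonds toward |χ3| ≈ 25°, where the
steep twofold χ3 term makes the excess strain unambiguous at 200 bonds per
cohort. Truncation is only ever planted on a protein's N-terminal bond so
it cannot silently invalidate other planted bonds. The truth tables are
derived from the planted states by a direct walk of the screening and
absence rules, independent of the mining code. Identical seeds yield
byte-identical fixture directories.

What the fixtures do *not* emulate: crystallographic noise and disorder,
alternate conformations beyond the altLoc parsing tests, radiation-induced
bond cleavage, biological assemblies, and chimeric chains. Passing the
planted-truth tests therefore demonstrates the pipeline's logic is exact on
clean inputs, not that real-corpus numbers are insensitive to data quality.

## Problem sizes and determinism

The default test corpus is 20 proteins × 4 structures (~80 files, ≤110
residues each) and the effect cohorts are 200 bonds per arm — sizes at
which every statistic is stable and the whole suite runs in seconds. All
randomness flows through seeded `numpy` generators; scan outputs are fully
sorted by (accession, pos_i, pos_j, pdb_id, chain) so re-running on
unchanged inputs is byte-identical.

## Known limitations

- Legacy PDB format only; mmCIF is out of scope by design (SSBOND header
  lines are the declared bond evidence this method is built on).
- Secondary structure comes from HELIX/SHEET header records, not a
  geometric re-assignment; a per-residue table can be substituted.
- One canonical sequence per accession; chains mapping to several
  accessions are excluded with a logged reason.
- Reducing-agent detection is a heteroatom-code blocklist; a free-text
  scan of crystallisation remarks is not enabled by default.
- Whether SSBOND records of asymmetric-unit files or biological assemblies
  are the better bond evidence is an open modelling question; asymmetric-
  unit files are assumed.
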