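# Methods

This note documents the models, conventions and numerical choices behind
`secretominer`, in enough detail to reproduce or audit any stage.

## Secretion decision rule

The rule is a conjunction of five per-protein criteria, each recorded
separately so a failed call is attributable:

| criterion | definition | source of the call |
|---|---|---|
| `sp_present` | signal peptide predicted | SignalP-style evidence |
| `tm_ok` | zero TM helices, or exactly one with start ≤ cleavage position | TMHMM-style evidence |
| `targetp_ok` | localization class `S` (secretory) | TargetP-style evidence |
| `wolfpsort_ok` | top-ranked compartment is `extr`; ties at rank 1 pass if `extr` is among them | WoLF PSORT-style evidence |
| `kdel_ok` | C-terminal tetrapeptide is not an ER-retention motif | computed from the sequence |

All five criteria are always evaluated (no short-circuiting), so the reason
log is complete even for early failures; the conjunction is trivially
monotone. Design choices where the underlying geometry is not fully
determined by predictor output:

- **TM/signal overlap.** A single helix is compatible iff its start is at or
  before the predicted cleavage position. The cleavage position is the only
  signal-peptide boundary the predictors expose, so "overlap" is anchored
  there rather than on an inferred h-region.
- **ER retention.** Two motif modes: `strict_kdel` (literal K-D-E-L) and
  `ps00014` (the PROSITE ER_TARGET pattern `[KRHQSA]-[DENQ]-E-L`). The
  default is `ps00014` — the pattern behind the scanning tool whose accession
  the field's pipelines cite — with the strict variant one flag away.
  Sequences shorter than 4 residues cannot carry the motif and pass.
- **SSP threshold.** Strict `length < 300` on the full precursor (signal
  peptide included); no mature-chain correction is attempted because cleavage
  positions from short-format predictor output are not reliable enough to
  subtract.

Evidence parsers accept the short/tabular dialects of SignalP 4.1, TMHMM 2
(one-line `PredHel`/`Topology`), TargetP 1.1 (non-plant table) and WoLF PSORT
(ranked compartment-score line). SignalP's printed Ymax position is the first
mature residue; we store position − 1 as the last signal-peptide residue.
Proteins absent from any of the four files are excluded with a warning.
None of these tools reports ER retention, so the decision rule always rescans
the sequence itself.

## Functional categorization

Per database (CAZy, MEROPS, LED, PFAM) the best hit is the smallest e-value
at or below the cutoff (default 1e-5, inclusive), ties broken by larger
bitscore then lexicographic subject label. The category is the database of
the overall smallest e-value among CAZy → CAZyme, MEROPS → Protease, LED →
Lipase; residual ties fall back to that database order. PFAM hits never
drive the category; they populate the domain list used by enrichment.
Proteins without any qualifying hit are SSP when the size flag is set, else
Other, and the SSP flag is additionally stored independently of category (a
small lipase is both).

The protease endo/exo mapping ships as a data file (default: endo = A01,
M36, S53, S28; exo = S08, S09, M28, following the figure legend that labels
the plotted data; the alternative assignment that appears in the
accompanying text is one edit away). Families outside the mapping are
`unassigned`, so endo + exo + unassigned always partitions the proteases.

K/R-rich regions use a sliding window (default 20 residues, ≥ 40% K+R);
qualifying windows merge into maximal intervals. These two thresholds are
package conventions — the feature is named in the field without a standard
definition — and both are exposed. The optional NLS scan (monopartite
`K-[KR]-x-[KR]`) is a crude surrogate for a dedicated predictor and is off
by default.

## Pairwise identity and clustering

Identity is computed on one optimal global alignment under BLOSUM62 with
affine gaps (open 10, extend 1; the opening penalty covers the first gapped
column). Identity = identical aligned residue pairs / length of the shorter
sequence, matching the convention of greedy incremental clustering tools; an
alignment-length denominator is config-selectable. `X` never counts as a
match, though it aligns normally.

Greedy clustering processes sequences by length descending (ties by protein
id), joining the first existing cluster whose representative is matched at
identity ≥ threshold (default 0.70), else founding a new cluster. Because
the order and tie-breaks are total, the partition is independent of input
order, representatives are always longest members, and raising the threshold
can only split clusters. No k-mer prefilter is used: at desk scale direct
alignment against representatives is exact and fast, and any accelerator
would have to be behaviour-preserving.

Species-specific SSPs are those with no cross-species alignment passing a
Karlin–Altschul significance surrogate: bitscore = (λS − ln K)/ln 2 with the
gapped BLOSUM62 parameters λ = 0.267, K = 0.041, and e-value =
m·N·2^(−bitscore) with m the query length and N the total residue count of
other-species SSPs, thresholded at the annotation cutoff (1e-5). This stands
in for an all-vs-all search tool so tests need no external binary; it uses
the same alignment engine but only its raw score.

## Lifestyle partition and statistics

Registry lifestyles map onto four comparison groups (ECM, white rot, brown
rot, litter decayer); all other lifestyles (pathogen, orchid/ericoid
symbiont, endophyte, mycoparasite, yeast) collapse to `other`, which never
defines a Venn set. A cluster's region is the exact set of groups its member
species cover; specificity is ECM_only iff the composition is exactly {ECM},
saprotroph_only iff it is a non-empty subset of the three saprotroph groups,
shared_ECM_saprotroph iff ECM plus at least one saprotroph group and nothing
else. The grouping is a user-editable YAML file.

PFAM enrichment per lifestyle is a one-sided Fisher exact test on the 2×2
table (in-lifestyle vs elsewhere) × (has domain vs lacks domain) over
secreted proteins, Holm-adjusted across domains at alpha 0.01. Zero-margin
tables return p = 1 rather than erroring. The test and alpha align with the
corrections used for the other comparisons; both are parameters.

SSP proportions (SSP% of secretome, species-specific-SSP% of secretome) are
compared across lifestyles with at least five species, using pooled-variance
two-sample t-tests and two-sided Mann–Whitney tests, each Holm-adjusted
across pairs, with compact letter displays (insert-and-absorb) at alpha.
Identical constant groups short-circuit to p = 1 to avoid degenerate test
statistics. Secretome-size correlation is a per-lifestyle Pearson r (and
r²), reported as missing for groups with < 3 species or zero variance.

## Synthetic data generator

The generator emulates the statistical structure of a multi-species
proteome collection at desk scale. Defaults: 6 species cycling the four
lifestyle groups, 500 proteins per species, 8% secreted (the center of the
3–10% range typical of fungal proteomes), half of the secretome < 300 aa,
12% of the proteome carrying 1–7 transmembrane helices, 5% of the secreted
count added as KDEL-bearing decoys, 10% of secreted proteins given a single
helix overlapping the signal peptide (to exercise the TM exception), and
four planted SSP families at 0.85 expected pairwise identity. Background
residues are uniform over the 20 amino acids by default — identity nulls are
easiest to reason about uniformly — with a Robinson–Robinson-style frequency
table selectable.

Planting is exact (deterministic rounding of fractions) so tests are sharp;
a Bernoulli sampling mode exists for statistical work. All randomness flows
from one integer seed through spawned per-species streams, so regeneration
is byte-identical and partial changes (e.g. a different hit-table seed) do
not disturb the proteomes.

Generated signal peptides are M + 1–2 K/R, an 8–12 residue hydrophobic
h-region, and an A-X-A cleavage context; generated evidence tables reflect
the planted truth exactly, so the decision rule recovers the planted
secretome perfectly by construction — that invariant is what lets
end-to-end tests attribute any disagreement to the pipeline rather than the
data. Secreted sequences are patched never to end in an ER-retention motif
by chance. The built-in surrogate predictor (charge/hydrophobicity/cleavage
heuristics, Kyte–Doolittle 19-residue windows above hydropathy 1.6 for TM
helices) is deliberately simple, documented as non-equivalent to the
published tools, and used only for demos and robustness tests; the planted
evidence tables, not the surrogate, define ground truth.

**Family identity calibration.** `plant_ssp_family` mutates an ancestor
independently per member at per-site rate 1 − t, giving expected identity t
to the ancestor and expected pairwise identity t² + (1 − t)²/19 between
members (uniform substitution over the 19 alternatives). The simulation
config's `family_identity` is the target *pairwise* identity; the generator
inverts the formula to obtain the ancestor-level t (for pairwise 0.85,
t ≈ 0.922). Within proteomes, family members share the ancestor's signal
peptide and mutate only the mature region, keeping members detectable and
small. Families are recoverable by design whenever `family_identity` exceeds
the clustering threshold with margin: at 0.85 vs 0.70 the per-pair shortfall
probability is negligible for SSP lengths (σ ≈ 0.03 at 150 aa).

What the generator does **not** emulate: phylogenetic correlation between
species, indels and rate heterogeneity within families, compositional bias
of real signal peptides, genome annotation noise, or unconventional
(leaderless) secretion — which the decision rule cannot see by construction.
Passing tests therefore certify the pipeline's logic and statistics, not the
accuracy of any upstream predictor on real proteomes.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the generator at 150–500
proteins per species and 6–8 species, clustering sets of ≤ 50–120 SSPs —
sizes chosen so brute-force oracles (all-pairs identity, exhaustive
alignment enumeration on ≤ 8-mers, direct hypergeometric summation on all
2×2 tables with total ≤ 30) can verify every result exactly. Greedy
clustering is verified against its own membership rule by brute force over
200 random sets; planted-family recovery is measured over 20 seeds; the
enrichment null (all multipliers 1.0) is simulated over 200 seeds and the
raw per-test rejection rate at alpha 0.01 is required to stay within twice
nominal (Fisher's discreteness makes it conservative in practice).

Degenerate inputs: empty sequences are rejected at alignment; sequences
shorter than the K/R window yield no regions; single-species inputs to
species-specificity return everything with a warning; a species with zero
proteins aborts summarization. Output tables are plain TSV with
`#`-prefixed metadata headers recording every threshold; floats round-trip
(`%.17g` written, round-trip parsing on read), so re-running a stage on its
own outputs is bit-stable.

## Known limitations

- The five-way rule inherits every blind spot of its evidence: leaderless
  secretion is invisible, and real predictor errors propagate unchecked.
- The published cluster table ships as membership only (no sequences), so
  cluster-level analyses on it are partition/counting operations; identity
  clustering is exercised on synthetic and user data.
- The species-specificity e-value is a calibrated surrogate, not a drop-in
  reimplementation of a heuristic search tool; absolute e-values differ even
  though decisions at the 1e-5 cutoff are stable for clearly-related vs
  unrelated pairs.
- Printed-table inconsistencies in the source material (internal arithmetic
  of group counts) are preserved as printed, with group counts always
  recomputed from the registry rather than hard-coded.
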