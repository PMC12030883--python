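# Methods

This note records the modeling choices behind `respiscreen`: what each
component assumes, which parameters matter and why their defaults are what
they are, what the synthetic benchmarks do and do not demonstrate, and where
the known limitations lie.

## Curation pipeline

Hazard datasets assembled from GHS classification inventories arrive as
heterogeneous SMILES with salts, mixtures and inorganics.  The pipeline
applies, in order:

1. **Desalting** — a multi-component structure is split; fragments without a
   carbon atom (metal counterions, water, halide ions) are discarded.
2. **Mixture rejection** — if more than one carbon-containing component
   remains after desalting, the record is a true mixture and is rejected.
   Structures with no carbon at all are rejected as inorganic.
3. **Element filter** — any atom outside {H, B, C, N, O, F, Si, P, S, Cl,
   Se, Br, I} marks the record as metallo-organic and rejects it.  Silicon
   is deliberately on the allowed list: chlorosilanes are respiratory
   irritants and appear in the packaged alert table.
4. **Neutralization** — simple ionized acid/base groups are
   protonated/deprotonated (RDKit's standardization uncharger).  Structures
   that remain charged (quaternary ammonium, charge-separated groups that
   cannot be neutralized without a valence violation) are kept as-is and
   noted in the rejection log; nitro groups stay in their charge-separated
   written form.
5. **Deduplication** — records are keyed by InChIKey of the standardized
   structure (canonical-SMILES fallback for the rare structure InChI cannot
   encode).  The stereo layer participates, so enantiomers are distinct.
   When duplicates disagree on the activity label the survivor is labeled
   **active**: in weight-of-evidence hazard data a positive call usually
   rests on direct observation while negative calls are often indirect, so
   positive wins.

Rejection is an accounted outcome, never an exception: every input record
lands in the curated output or in exactly one report category, and the
report is checked for consistency (`n_output = n_input − rejections −
merges`).

## Structural alerts

Alert patterns are **plain SMILES interpreted as substructure queries**:
atoms constrain element and aromaticity, bonds constrain order, and
implicit hydrogens are unconstrained, so every open valence is a wildcard
attachment point.  Two technical consequences:

- Radical electrons that the SMILES parser assigns to open-valence bracket
  atoms (e.g. a trivalent silicon in a chlorosilane fragment) are cleared
  when the query is compiled — they are artifacts of writing a substructure
  as a molecule, not constraints.
- A molecule matching one alert several times (two anhydride groups, say)
  counts **once** in all occurrence statistics; the unit of counting is the
  chemical, not the match.

Per-alert statistics are `N_Tot` (molecules containing the pattern),
`N_True` (those that are active) and `PPV = N_True/N_Tot`, undefined — never
coerced to 0 or 1 — when `N_Tot = 0`.  Set-level PPV pools molecules flagged
by **at least one** alert.  Alert-based prediction is one-sided: a match
means Active, no match means *Inconclusive*, because the absence of a known
alert is not evidence of safety.

## Fragment mining

### Fragment space

A fragment is a connected induced subgraph of the heavy-atom graph that is
**closed under ring bonds**: touching one atom of a ring system pulls in the
whole fused system.  For acyclic molecules this is exactly the set of all
connected induced subgraphs; rings are never sliced, so mined alerts can
contain intact rings but no ring slivers.  The enumerator contracts each
ring system to a super-node and enumerates connected subsets of the
contracted graph (ESU-style, each subset exactly once) with the atom-weight
cap applied during recursion; the test suite checks it against an
independent brute-force enumerator that walks the raw powerset.  Fragment
identity is canonical SMILES, stereo stripped, round-tripped through the
parser so that identical substructures from different parents compare
equal.

### Thresholds

- `min_atoms = 4`, `max_atoms = 20`: fragments below four heavy atoms are
  too generic to be meaningful alerts; beyond twenty they approach whole
  molecules.
- `min_support_active = 4`: a rule must occur in at least four active
  chemicals.
- `min_precision = 0.8` (configurable, surfaced in the CLI): the packaged
  alert sets show set-level precision ≥ 0.9, and 0.8 is the floor at which
  comparable per-rule precision emerges on synthetic benchmarks.

### Rule selection

Candidates are fragments meeting both floors on the **full** training set.
The covering loop repeatedly selects the candidate maximizing

    (precision, larger size, active support, lexicographic canonical text)

among those still matching at least one uncovered active, then marks its
actives covered; it stops when nothing new can be covered.  Two choices
here are deliberate and worth defending:

- **Specificity preference.**  Among equal-precision candidates the largest
  fragment wins.  The natural-looking alternative — prefer the smallest,
  most general fragment — fails in a characteristic way: a generic
  heteroatom-bearing chain such as `C-C-C-N` can straddle two chemically
  distinct toxicophores (an aliphatic amine class and an isocyanate class,
  say), tie or beat both on precision, and dominate both on support,
  swallowing two mechanisms into one uninformative rule.  Preferring the
  specific pattern keeps distinct toxicophores distinct; the cost is a
  longer rule list, since context-decorated variants of a motif may be
  emitted alongside it.
- **Support on the full set.**  Eligibility uses a fragment's support among
  *all* actives, not the not-yet-covered remainder.  Judging support on the
  remainder lets a specific variant that covers part of a class starve the
  class's true motif below the support floor before it can be selected.

Emitted rules carry `N_Tot`/`N_True`/PPV recomputed by substructure
matching over the full input set, so their statistics have exactly the
semantics of the packaged tables (enumeration containment implies a
substructure match, so recomputed support can only grow).

## Consensus classification

### Base models and featurization

The default consensus has five members: circular (Morgan radius-2, 1024-bit)
fingerprints × {random forest, logistic regression}, physicochemical
descriptors (14 RDKit descriptors: MolWt, MolLogP, TPSA, H-bond counts,
ring counts, etc.) × {random forest, gradient boosting}, and MACCS keys ×
scaled logistic regression.  Four- and five-member consensus models are
typical for these endpoints; the menu is fully configurable as
`(scheme, estimator)` pairs and the classifier composes with scikit-learn
pipelines and model selection.  Featurization is deterministic and
context-free: the same structure always yields the same row.

### Averaging and the applicability domain

Per-model output `y_jm` is the predicted probability of the Active class
(probabilities rather than hard votes preserve information and make the
disagreement statistic continuous).  The consensus score is the plain mean
`ȳ_j`; the decision threshold is 0.5.  Disagreement is

    CONS-STD_j = sqrt( (1/N) Σ_m ( ȳ_j − y_jm )² )

the population standard deviation of the member outputs (0 iff all members
agree; at most 0.5 for two members on [0, 1]).  During `fit`, every member
is cross-validated with the same stratified k-fold plan (k = 5, seeded),
giving each training molecule one out-of-fold probability per member; the
applicability-domain threshold defaults to the **95th percentile of the
cross-validated CONS-STD**, i.e. roughly 5 % of training-like chemicals
fall outside the domain by construction.  At prediction time a molecule
with CONS-STD above the threshold is *Inconclusive* regardless of its mean;
a molecule that cannot be parsed or featurized is likewise Inconclusive
with a logged reason, never an exception mid-screen.  Optional greedy
forward selection on out-of-fold AUC ("keep a member only if it improves
the consensus") is implemented but off by default — all configured members
participate.

### Evaluation

ACC, SEN and SPE come from the confusion matrix with undefined ratios
reported as missing rather than 0; AUC is the rank-based probability that a
random active outranks a random inactive, ties counting one half.  The
train/test split is stratified with `|train| = round(0.8·N)`; all
randomness flows from a single seed.

## Confidence-score integration

The alert call (Active/Inconclusive) and the model call
(Active/Inactive/Inconclusive) combine into {2, 1, 0, −1} as tabled in the
README.  The pair (no alert, model Inactive) has no published score; it is
reported as **NA / Predicted-inactive** rather than overloading 0, which is
reserved for the doubly-Inconclusive case.  The mapping is total and
deterministic, and every screening run verifies the set identities
`score-2 = alert-Active ∩ ML-Active` and `score-(−1) = alert-Active ∩
ML-Inactive` plus count conservation across the five score bins.

## Synthetic benchmarks

The generator emulates a curated binary hazard set with exact ground truth:

- **Actives** are alert-free scaffolds with one chosen motif grafted on via
  a single bond at a free-valence carbon (motif side prefers a carbon so
  the heteroatom core stays intact); the motif is thus an exact subgraph.
- **Inactives** are motif-free scaffolds.  The scaffold pool is ~30 plain
  hydrocarbons and aliphatic ethers verified against both packaged alert
  tables; methyl decoration for structural diversity cannot create an alert
  match because every packaged alert contains a heteroatom arrangement.
- **Noise**: `planting_noise` is the fraction of actives carrying no motif
  (label noise in the positive class); `decoy_noise` the fraction of
  inactives carrying one.  Counts are deterministic
  (`round(rate · n)`), and output is byte-identical for identical
  configuration.
- Defaults (60 + 60 molecules, three motifs drawn from the packaged
  tables, zero noise) represent a small, clean curated set — large enough
  that each motif has well over the mining support floor, small enough for
  fast exhaustive checks.

A second generator produces **feature-separable** sets from two structure
families (brominated vs hydroxyl/ether) whose fingerprint supports are
disjoint at separation 1.0 and label-independent at 0.0, for benchmarking
the consensus machinery without the mining layer.

**What passing these benchmarks shows — and does not.**  Synthetic actives
differ from inactives by a planted substructure, so they demonstrate the
machinery's correctness (recovery of known motifs, calibration of the
domain gate, conservation of screening counts), not field performance.
Real respiratory toxicants are not defined by single substructures; real
inactive sets contain heteroatom-rich molecules that make mined-rule
precision much harder to achieve than on hydrocarbon scaffolds; and real
label noise is not independent of structure.  Accuracy figures obtained on
synthetic sets therefore do not transfer to real GHS-derived data.

## Numerical and degenerate-input conventions

- Undefined ratios (PPV with no occurrences, SEN with no actives, AUC with
  one class) are explicit `None`/error outcomes, never silently 0, 0.5 or 1.
- All tie-breaks in mining are total (final key: canonical fragment text),
  so identical input and configuration reproduce identical rule lists.
- `round()` banker's rounding is harmless for the 0.8 split (0.8·N never
  ends in .5) and is used as-is for noise counts.
- Atom counts everywhere mean heavy (non-hydrogen) atoms.
- Problem sizes in the shipped benchmarks (planted sets of 60–400
  molecules, 20 mining seeds, 10 modeling seeds) were chosen to give stable
  pass/fail margins on commodity hardware.

## Known limitations

- The curation step implements the named rules (desalting, neutralization,
  mixture/inorganic/metallo-organic removal); it is not a full QSAR-ready
  standardization workflow (no tautomer canonicalization, no functional
  group normalization beyond charge).
- Alert patterns are matched as written; no hydrogen-count or degree
  constraints are added, so some patterns are more permissive than a
  hand-elaborated SMARTS would be.
- The miner's specificity preference can emit context-decorated variants of
  a toxicophore alongside the toxicophore itself; post-hoc pruning of rules
  whose match set is contained in another rule's is left to the analyst.
- The consensus applicability domain covers the consensus only; per-member
  applicability domains are not modeled.
- Descriptor parity with commercial packages (Dragon, Mold2, Mordred
  et al.) and neural/graph learners are out of scope; the featurizer
  registry is generic and extensible instead.
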