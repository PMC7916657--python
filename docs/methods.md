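# Methods

## Model

A causal network is a signed directed multigraph: nodes are genes, proteins,
fusion proteins (one node per fusion, e.g. `PML-RARalpha`) or hallmark
phenotypes; edges carry +1 (up-regulates) or −1 (down-regulates). Phenotype
nodes — `proliferation`, `differentiation`, `apoptosis` by default,
overridable — are sinks. A pair of nodes may be connected by both an
activating and an inhibiting edge; the graph keeps both and defers the
conflict to rule synthesis.

### Rule synthesis

Each node `v` with activator set `A` and inhibitor set `I` receives a
Boolean update rule:

| A | I | inhibitor-wins | activator-wins |
|---|---|----------------|----------------|
| ∅ | ∅ | `v` (holds its value) | `v` |
| ≠∅ | ∅ | `OR(A)` | `OR(A)` |
| ∅ | ≠∅ | `NOT OR(I)` | `NOT OR(I)` |
| ≠∅ | ≠∅ | `OR(A) AND NOT OR(I)` | `OR(A)` |

Same-sign inputs always combine with OR. The no-input default is off: a node
whose regulators are all inactive deactivates, except regulator-free source
nodes, which hold their initial value — this keeps every rule a pure
function of the state while letting source nodes act as boundary
conditions. Inhibitor-only nodes are constitutively active when uninhibited;
otherwise their inhibitors could never matter. A regulator carrying both
signs appears in both `A` and `I`; under inhibitor-wins its activity forces
the target off. Experimentally established gates can replace any
synthesized rule verbatim via `overrides` (expression trees or rule-dialect
strings).

### Genotypes and dynamics

A genotype is a set of lesions: LOF clamps a node's rule to the constant 0,
GOF to 1; clamps persist for the whole simulation and priming is
idempotent. Updates are synchronous only (matching the standard Boolean
network simulation convention this tool targets). Attractors are found
either exhaustively — full transition graph over the `2^f` states of the
`f` free nodes, exact basin sizes, bounded at 25 free nodes by default — or
by trajectory iteration from a given or seeded-random initial state until a
state repeats. Fixed points satisfy `F(s) = s`; cycles are stored rotated to
their lexicographically smallest state. Per-node activation is the state
value at a fixed point and the arithmetic mean over cycle states otherwise,
so downstream scoring is total; cyclic attractors are flagged through the
non-integer values and `n_attractors` bookkeeping.

### Phenotype scores

At equilibrium each hallmark `P` is scored additively over its *direct*
regulators: `score(P) = Σ act(a) − Σ act(i)`, bounded by
`[−|I(P)|, |A(P)|]`; a normalized variant divides each sum by its regulator
count. The integrated network phenotype score is
`proliferation − apoptosis − differentiation`. When a genotype yields
several attractors, scores are reported per attractor and the headline value
is their basin-weighted mean, flagged as aggregated; raw (unnormalized)
scores are the default for correlation.

### Driver classification

All simple paths from a gene to each hallmark are enumerated (networkx
`all_simple_paths` on the node skeleton, expanded per parallel-edge sign
combination); a path's net sign is the product of its edge signs, so an
inhibitor of an inhibitor acts as a net activator. Path length is
unbounded by default — curated disease networks are small (~80 nodes) —
and configurable. Oncogenic evidence: (proliferation, +), (differentiation,
−), (apoptosis, −); suppressor evidence is the mirror set; both → dual,
neither → unclassified. Cycles never contribute: a path through a feedback
loop has no well-defined sign. A useful sanity property, asserted in the
tests: since every simple path to a hallmark traverses exactly one
phenotype-incident edge, flipping the signs of exactly those edges negates
all path signs and swaps oncogene ↔ tumor-suppressor labels while fixing
dual/unclassified. (Flipping *all* edge signs has no such effect:
even-length paths keep their sign.)

### Clinical correlation

Model scores are correlated with clinical features at the genotype-class
level — the only granularity the model produces (8 classes for a
three-gene module) — via the Pearson product-moment coefficient
(scipy.stats). Constant vectors raise rather than silently returning 0; no
p-values are attached by default at such small n, since correlation
strength is the readout.

## Packaged module and fixtures

The FLT3-NPM1-DNMT3A module is a **synthetic reconstruction**: 21 protein
nodes and the 3 hallmarks, wired from canonical AML signaling biology —
FLT3 receptor signaling through STAT5 (→ BCL2, MYC), PI3K-AKT-mTOR
(⊣ FOXO3, → MDM2) and RAS-RAF-MEK-ERK (→ MYC, ⊣ CEBPA); NPM1 stabilizing
the ARF(CDKN2A)-MDM2-p53 axis; DNMT3A repressing the HOXA9-MEIS1
self-renewal program; CEBPA/SPI1 driving and HOXA9 blocking
differentiation. It is not a transcription of any published rule table, and
no AND-gate overrides are asserted for it. The wiring is feedback-free, so
every genotype reaches a unique fixed point from any initial state. Fixture
files are checksum-pinned in the tests.

The wild-type initial condition is the package's own choice (nothing forces
one): unclamped nodes start at 0 except the source nodes NPM1 and DNMT3A,
constitutively expressed in healthy hematopoietic cells, which start (and
therefore stay) at 1, with FLT3 off absent ligand. This makes wild-type
reflect intact tumor-suppressor signaling: differentiation and apoptosis
scored positive, proliferation negative.

The toy driver-list collection contains four lists of real AML driver-gene
symbols arranged so that exactly 31 genes appear in ≥ 2 lists; the
connectivity additions (MYC, ETV6, CBFB) and six onco-fusion names bring
the driver set to 40. The lists are fixtures for the consensus operation,
not faithful copies of any resource release.

## Synthetic data generators

`generate_network` draws random signed graphs (edge density, inhibition
fraction, optional feedback, phenotype sinks guaranteed ≥ 1 regulator),
deterministically from a seed. `generate_clinical` builds a feature as
`slope · integrated + N(0, sd²)` — Gaussian noise being the simplest
mean-zero model for correlation-recovery checks. These emulate the
*structure* of curated networks and cohort features, not their biology: no
literature-derived wiring, no mutation co-occurrence statistics, no
survival-model realism. Passing property tests therefore demonstrates
correctness of the machinery (attractor search, score bounds, classifier
duality, correlation recovery), not clinical validity on real cohorts.

## Numerical and design choices

- Determinism: every stochastic step (random networks, random starts,
  clinical noise) takes an explicit integer seed; reports embed their
  resolved configuration so a run reproduces byte-identically.
- Property-test problem sizes: random models are kept at ≤ 12 free nodes so
  exhaustive transition graphs (≤ 4096 states) stay exact and cheap;
  ensembles of 100–200 seeds give coverage without heavy runtimes.
- Low-noise correlation recovery uses noise sd 0.3 against an integrated
  score spanning [−5, 6] (sd ≈ 3.7), i.e. a signal-to-noise regime where
  r ≥ 0.9 is expected on every seed.
- Ties and ordering: sweep genotypes enumerate in binary-counting order over
  the given lesion list (wild-type first); genotype labels sort lesions
  alphabetically; SIF and rules files are written in sorted order.
- Degenerate inputs raise early: empty gene-list collections, constant
  vectors in correlation, genotype genes absent from the model, exhaustive
  search beyond its bound (with a pointer to trajectory mode).

## Limitations

- Synchronous updating only; no asynchronous or probabilistic schemes.
- The additive phenotype score ignores indirect regulation of hallmarks.
- The packaged module is a plausible reconstruction; conclusions about the
  real FLT3/NPM1/DNMT3A axis require a curated network as input.
- Classification counts all simple paths equally; no path weighting or
  length discounting.
- Clinical correlation at genotype-class level has very small n by design;
  it quantifies agreement, not significance.
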