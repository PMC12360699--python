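# Methods

## Scope and model

`bcrlik` analyses how per-residue likelihoods from masked protein language
models relate to signatures of B cell selection in single-cell BCR
repertoires. The pipeline has five analytical layers:

1. **Pseudolikelihood scoring.** A likelihood provider maps an amino-acid
   sequence to an L×20 row-stochastic matrix of per-residue likelihoods (RL).
   The sequence pseudolikelihood (SP) is the mean natural-log probability of
   the observed residues over the scored positions,
   `SP = (1/|P|) Σ_{i∈P} ln p_i(x_i)`. Three input sources vary the context:
   the full V(D)J sequence (all positions scored), CDR3-from-VDJ (full-context
   matrix, only CDR3 positions averaged), and CDR3-only (matrix computed from
   the bare CDR3 string). Paired scoring takes a single mean over all heavy
   plus light positions, heavy first.
2. **Repertoire ingestion.** AIRR Rearrangement TSV or CellRanger-style
   contig CSV; five hygiene filters (multi-transcript cells, incomplete
   cells, missing heavy germline, missing heavy C gene, cross-sample
   duplicated barcodes) applied in that order with per-rule counts. SHM is
   the Hamming distance to the (pre-trimmed) germline; chains whose germline
   length differs (indels) are excluded from SHM and edge analyses rather
   than re-aligned, since Hamming distance is undefined there.
3. **Lineage forests.** Per clone, unique sequences grow from the germline
   root by iterative minimum-Levenshtein attachment (Prim's algorithm on the
   complete edit-distance graph), so total tree weight equals the MST weight
   whatever the attachment order. Edit distances come from edlib.
4. **Edge-substitution statistics.** For equal-length edges the parent
   sequence is scored and each substituted position contributes the
   descending rank of the child's residue in the parent's column
   (competition ranking: 1 + number of strictly greater entries, so the
   argmax is rank 1 even under ties). Multi-substitution edges report the
   mean rank. The conserved-vs-mutating contrast compares the parent's own
   residue likelihood at substituted versus identical positions, with a
   paired t-test across edges. Shannon evenness of a column is `H/ln 20`.
5. **Association battery.** Pearson/Spearman correlations of SP with SHM,
   normalized clonal expansion (cells per clone / sample size) and
   root-path distance; Welch t-tests between isotypes with Holm adjustment
   (Bonferroni and Benjamini–Hochberg selectable); correlation of group mean
   SP against an external frequency table; SP–Kd Spearman correlations at
   polyclonal or intraclonal scope. Signed correlations are reported as
   r/rho. Sample-level summaries are unweighted means of per-sample
   statistics, averaged on the plain r scale (no Fisher transformation),
   so every sample counts equally regardless of cell count.

## Synthetic study conditions

The generator emulates the structure the analyses assume, not germinal-center
biophysics:

* **Clone sizes** follow a discrete power law `P(s) ∝ s^-α` truncated at the
  sample size, α = 2.5 by default — heavy-tailed enough to give both
  expanded clones and a large singleton mass, as real repertoires show.
* **Maturation stages.** Each cell draws an independent stage
  `t ~ Uniform{0..max_shm_rounds}`; its lineage parent is chosen uniformly
  among already-generated clone members of stage ≤ t (germline always
  eligible) and `t − t_parent` SHM rounds are applied on the edge, each
  substituting `per_round_substitutions` uniformly chosen positions (no
  indels; replacement uniform over the 19 alternatives, or drawn from a
  provider's column under the `provider_guided` strategy). Independent
  stages keep per-cell SHM decoupled from clone size by construction, which
  is exactly the null the expansion analysis must not reject; the
  parent-selection rule still yields branching germline-rooted truth trees
  and expanded identical-sequence nodes. Light chains mature at half the
  heavy-chain rounds (rounded down).
* **Isotype switching** occurs per heavy-chain SHM round with probability
  `switch_coupling` (default 0.3); once switched (IgG with probability 0.75,
  else IgA) the state is inherited, so class-switched cells carry more SHM
  on average.
* **Affinity** is `log10(Kd) = −8 − coupling·SHM + N(0, σ)`: unmutated cells
  sit at 10 nM and maturation strengthens binding, the direction the
  intraclonal analysis is designed to detect.
* **Defaults**: 1000 cells, 8 germline pairs, 110-aa V(D)J with CDR3 at
  positions 95–107, up to 8 rounds × 2 substitutions, switch coupling 0.3,
  affinity coupling 0.2 log10 units per substitution with σ = 0.3.

Two synthetic providers make every analysis testable in closed form. The
**germline-anchored provider** puts probability `q` (default 0.7, the
regime where SP magnitudes match antibody-LM outputs) on the germline
residue and `(1−q)/19` elsewhere, so SP is exactly linear in the number of
germline mismatches — the germline-bias mechanism believed to drive the
negative SP–SHM relationship in real models. The **Dirichlet-column
provider** draws each column from Dirichlet(0.3) seeded by a stable hash of
(seed, sequence, position): deterministic, context-sensitive, and spiky.
Rank-recovery contrasts need it, because the germline-anchored provider's 19
alternatives are equiprobable and carry no rank signal.

### What the generator does not emulate

No AID/polymerase hotspot motifs, no nucleotide level, no indels, no
germinal-center population dynamics, no shared germline database across
samples. Passing tests therefore demonstrate that the pipeline's statistics
recover the couplings present in the data — not that real repertoires have
those couplings, nor that real language models behave like the synthetic
providers.

## Numerical choices

* Natural log throughout (log2 selectable); probabilities of exactly zero
  are clamped to 1e-10 before the log and the event is loggable.
* Probability-matrix rows must sum to 1 within 1e-6; evenness uses the
  convention 0·ln 0 = 0.
* Tree tie-breaks: smallest distance, then larger candidate-parent cell
  count (expanded intermediates are likelier ancestors), then
  lexicographically smaller child sequence, then earlier attachment —
  fully deterministic.
* Competition ranking keeps "most likely ⇒ rank 1" exact under ties.
* Clonotype assignment (when no clone labels are supplied) is identity of
  (heavy V family, light V family, heavy CDR3, light CDR3); the simulator's
  truth labels are used when present, since CDR3-touching mutations can
  split identity-based clonotypes.
* Degenerate inputs: empty repertoires are valid for filtering but errors
  for expansion; zero-variance vectors flag the correlation rather than
  raising; identical groups report t = 0, p = 1.

## Design decisions that were genuinely open

* **Edge rounds per cell** (unspecified upstream): independent uniform
  stages, as motivated above.
* **Germline edges** in the substitution analysis: included by default (the
  germline is a valid parent sequence and root edges are where most
  mutations live); `include_germline_edges=False` restricts to
  sampled-sequence parents.
* **Duplicated barcodes**: interpreted as the same barcode under more than
  one sample; all copies are removed, none deduplicated.
* **Paired input ordering**: heavy then light; providers receive both
  strings and may concatenate internally.
* **Problem sizes**: the bundled study uses 1000 cells for the directional
  battery, 400-cell repertoires for the rank contrast (≈300 scorable edges)
  and 200 cells for the affinity analysis — large enough that the
  directional effects dominate sampling noise by an order of magnitude,
  small enough to run interactively.

## Known limitations

Exact tree topologies on tied distances are implementation-specific;
aggregated edge statistics are robust to this, per-node claims are not.
The CDR3-substring registration of the germline-anchored provider assumes
distinct clones do not share a CDR3 string with conflicting germlines
(collisions keep the first registration). Real-PLM adapters are provided as
an optional extra and are not exercised by the test suite.
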