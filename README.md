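# bcrlik

Masked-language-model pseudolikelihood analysis of single-cell B cell
receptor (BCR) repertoires.

Antibody and general protein language models assign every residue of a
sequence a probability; averaging the log probabilities gives a sequence
pseudolikelihood, `SP = (1/L) Σ_i ln p_i(x_i)`. `bcrlik` is for
immunologists and computational biologists who want to relate such scores to
signatures of in vivo B cell selection — somatic hypermutation (SHM),
isotype usage, clonal expansion, binding affinity — at single-cell
resolution. It provides:

* **Scoring** of paired heavy/light V(D)J amino-acid sequences under any
  likelihood provider (an object returning an L×20 row-stochastic matrix),
  with three input sources: full V(D)J, CDR3-from-VDJ (full context, CDR3
  positions scored) and CDR3-only, plus joint paired-chain scoring. Two
  synthetic providers ship with the package — a germline-anchored provider
  with closed-form SP and a deterministic Dirichlet-column provider —
  and optional HuggingFace adapters (`pip install bcrlik[plm]`) expose real
  models behind the same contract.
* **Ingestion** of AIRR Rearrangement TSV / CellRanger-style contig CSV with
  the standard hygiene filters, clonotyping, and Hamming-distance SHM.
* **Lineage forests**: germline-rooted trees per clone grown by iterative
  minimum-Levenshtein attachment (equivalently, minimum spanning trees of
  the clone's edit-distance graph), with Newick export.
* **Edge-substitution statistics**: the rank of each observed SHM
  substitution within the parent sequence's probability column, the
  conserved-vs-mutating residue likelihood contrast, and Shannon evenness
  of per-position probability distributions.
* **Association analyses**: SP against SHM, expansion, root distance,
  isotype (Welch tests, Holm-adjusted), external frequency tables, and Kd.
* A **synthetic repertoire generator** with full mutational ground truth, so
  the entire pipeline runs and is tested without sequencing data or model
  weights.

## Worked example

Simulate a repertoire, score it with the germline-anchored provider
(probability q = 0.7 on the germline residue), and correlate SP with SHM:

```python
from bcrlik import (
    GermlineAnchoredProvider, InputSource, SimulationConfig,
    build_forest, correlate, score_repertoire, simulate_repertoire,
    sp_feature_table,
)

sim = simulate_repertoire(SimulationConfig(n_cells=1000, seed=20))
rep = sim.to_repertoire()
provider = GermlineAnchoredProvider.from_cells(rep.cells, q=0.7)
scores = score_repertoire(rep, provider, [InputSource.FULL_VDJ])
forest = build_forest(rep, chains="heavy")
table = sp_feature_table(scores, rep, trees=forest)
heavy = table[(table.locus == "heavy") & (table.source == "full_vdj")]

print(correlate(heavy.sp, heavy.hamming_shm, "pearson").estimate)
print(heavy.groupby("isotype").sp.mean())
```

```
-1.0
isotype
IgA   -0.691101
IgG   -0.698967
IgM   -0.490650
Name: sp, dtype: float64
```

SP falls linearly with mutation load (for this provider the relationship is
exact, hence r ≈ −1), and unswitched IgM cells — which carry less SHM —
score higher than class-switched cells, the germline-bias signature these
analyses are built to expose.

The same pipeline runs from the shell:

```bash
bcrlik demo --out-dir runs/demo --seed 3        # one-command end-to-end run
bcrlik simulate --out-dir data --seed 1
bcrlik ingest --in data/repertoire.airr.tsv --out runs/rep
bcrlik score --repertoire runs/rep --q 0.7 --out runs/scores
bcrlik trees --repertoire runs/rep --out runs/trees
bcrlik shm --repertoire runs/rep --out runs/shm
bcrlik stats --scored runs/scores --repertoire runs/rep --out runs/stats
```

Every run directory ends with a `manifest.json` listing each artifact with
its SHA-256 hash; identical configurations reproduce byte-identical outputs.

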