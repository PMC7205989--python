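# metagenehunt

Domain-level functional annotation of short-read metagenomes processed with
MG-RAST, in the style of the MetaGeneHunt approach: instead of crediting a
read to whatever annotated protein it matched, decide *where on the protein*
the alignment actually fell.

## The problem

Short-read annotation pipelines assign a read to a reference protein from a
local alignment. But many proteins — glycoside hydrolases (GHs) and other
carbohydrate-active enzymes especially — are multidomain mosaics: a read
matching a "GH13-containing protein" may in fact cover a linker, a signal
peptide, a carbohydrate-binding module, or an unrelated accessory domain.
Counting such hits toward GH13 confounds local similarity with function and
systematically overestimates long domains.

This package resolves hits to specific domains and corrects the two
resulting biases:

1. **Localization.** Each 12-column tabular alignment hit (an MG-RAST
   "650" similarity record, with subject coordinates in amino-acid space)
   is intersected with the HMM-envelope coordinates of every domain on its
   subject protein, looked up by protein MD5 in a *reference annotation
   table* (RAT). If more than a cutoff `c` (default 20 AA) of the alignment
   falls inside an envelope, that domain's annotation is transferred to the
   read (`IN_DOMAIN`); if more than `c` aligned AA fall outside every
   envelope the hit is a negative (`OUT_OF_DOMAIN`); otherwise it is
   `UNCLASSIFIED`. Formally, for alignment interval `[a₁, a₂]` and envelope
   `[e₁, e₂]` (1-based, inclusive):

   ```
   overlap = max(0, min(a₂, e₂) − max(a₁, e₁) + 1),   transfer iff overlap > c
   ```

2. **Counting.** Per-hit read counts come from the MG-RAST "330"
   sequence-agglomeration file (a cluster representative stands for
   1 + members reads). Per-domain counts `n_d` are then length-normalized,

   ```
   n_d' = n_d × L_ref / L_d
   ```

   with `L_d` the domain's canonical (Pfam model) length and `L_ref` the
   longest domain considered (805 AA — GH70 — for the canonical GH table),
   and rarefied to a common depth by multivariate hypergeometric
   subsampling without replacement.

Downstream, the package provides Bray–Curtis dissimilarity
(`1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ)`), complete-linkage clustering, Shannon
diversity (`H = −Σ pᵢ ln pᵢ`), and the structure-vs-function comparison
(correlating taxonomic against functional pairwise dissimilarities within
sample groups). A synthetic-data module generates RATs, similarity and
cluster files with constructive ground truth, so the whole pipeline is
testable offline; real inputs can optionally be fetched from the MG-RAST
API.

## Worked example

```python
from metagenehunt import RAT, DomainEnvelope, SimilarityRecord, classify_hit

rat = RAT(lengths={"GH13": 450})
rat.add(DomainEnvelope("prot1", "GH13", 100, 300))
hit = SimilarityRecord("read_a", "prot1", 92.0, 71, 2, 0, 1, 100,
                       280, 350, 1e-12, 88.0)
res = classify_hit(hit, rat.envelopes_for("prot1"), cutoff=20)
print(res.classification.value, res.assigned_domain, res.overlap_aa)
# IN_DOMAIN GH13 21
```

The alignment covers subject residues 280–350; 21 of them (280–300) sit
inside the GH13 envelope — one more than the cutoff — so the annotation is
transferred. Shift the alignment one residue right and the overlap drops to
20: the read becomes `OUT_OF_DOMAIN`, because 50 of its residues align past
the envelope.

Running `python examples/04_length_bias.py` (uniform read coverage over 30
domains of 50–805 AA, 50,000 reads through the full localizer) prints:

```
raw counts vs domain length:        Spearman rho = +0.991 (p = 1.1e-25)
normalized counts vs domain length: Spearman rho = +0.034 (p = 0.86)
```

Raw hit counts track domain length almost perfectly — the length bias —
and multiplying each count by `L_ref/L_d` removes the association entirely.
The other scripts in `examples/` walk through hit classification, the full
sample-profile pipeline, and the community analytics.

## Command line

A thin CLI mirrors the pipeline stages:

```bash
metagenehunt synth --outdir fixtures/ --n-reads 5000 --seed 3
metagenehunt annotate --sim fixtures/sample.650.tsv --clusters fixtures/sample.330.tsv \
    --rat fixtures/rat.tsv --lengths fixtures/lengths.tsv -o hits.tsv --counts-out raw.tsv
metagenehunt normalize --counts raw.tsv --lengths fixtures/lengths.tsv -o norm.tsv
metagenehunt rarefy --counts norm.tsv --depth 99922 --seed 1 -o rare.tsv
metagenehunt profile --counts rare.tsv -o dist.tsv --tree tree.nwk
```

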