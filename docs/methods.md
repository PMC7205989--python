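# Methods

## Model and procedure

The package treats domain-level annotation of a short-read hit as an
interval-intersection problem on the reference protein's amino-acid axis.
Three inputs meet in the localizer:

* a **reference annotation table (RAT)** mapping each reference protein
  (by sequence-MD5 identifier, the M5nr convention) to the HMM-envelope
  interval of every domain occurrence on it, with a companion table of
  canonical (Pfam model) lengths per domain family;
* **similarity records** in the 12-column BLAST tabular layout, whose
  subject coordinates for translated searches are amino-acid positions on
  the reference protein;
* a **cluster map** giving, for each similarity query that is a cluster
  representative, the number of reads agglomerated under it.

For each hit the overlap with every envelope of its subject protein is
`max(0, min(a₂,e₂) − max(a₁,e₁) + 1)` on 1-based inclusive intervals. The
decision rule is strict-greater against a configurable cutoff (default
20 AA, i.e. 21 AA of overlap suffice): transfer the annotation of the
largest-overlap domain when any domain clears the bar, otherwise declare
the hit a negative when more than the cutoff of its aligned residues are
covered by no envelope, otherwise leave it unclassified. The out-of-envelope
residue count is computed on the union of envelopes, so overlapping
subdomain envelopes (GH3C inside a GH3 region, say) are not double-
subtracted.

Assumptions worth stating: subject coordinates are trusted as reported
(no realignment, no frameshift handling); query nucleotide coordinates are
ignored — overlap is only well-defined on the protein axis; one hit yields
at most one domain assignment.

## Design choices where the procedure was open

* **Multi-domain resolution.** A read clearing the cutoff for two domains
  is assigned to the single largest-overlap domain, with ties broken
  lexicographically by domain id and an `ambiguous` flag set. Assigning to
  both would double-count a single read toward two families; dropping such
  reads would bias against multidomain proteins. The flag lets downstream
  analyses filter if desired.
* **Precedence.** A read exceeding the cutoff both inside and outside an
  envelope is IN_DOMAIN: the negative rule is read as applying to reads
  that lack sufficient in-domain overlap.
* **Per-family overlap across tandem repeats** uses the maximum over that
  family's envelopes, not the sum: a read bridging two short occurrences of
  the same family must clear the cutoff within one occurrence.
* **Best-hit policy.** Similarity files may carry several hits per query;
  by default only the best hit (highest bit score, then lowest e-value,
  then smallest subject MD5 — a total order, so the choice is independent
  of file order) enters localization, matching abundance-profile practice.
  An all-hits mode exists for diagnostic use.
* **Cluster multiplicity** is 1 + number of members: the representative is
  itself a read.

## Quantification

Per-domain raw counts sum the cluster multiplicities of IN_DOMAIN hits.
Length normalization multiplies each domain's count by
`L_ref / L_d`; the reference defaults to the longest domain present in the
table and can be pinned (805 AA, GH70, for the canonical GH reference
table, whose packaged length entry is the one normalization constant the
package ships). The factor for the longest domain is exactly 1, so
normalization only scales counts up.

Rarefaction draws each sample row to a fixed depth without replacement
(multivariate hypergeometric, numpy's `marginals` method) under one
explicit seed. Normalized real-valued counts are rounded
half-away-from-zero to integers first — rarefaction is defined on
multisets — introducing at most 0.5 error per cell; a note is emitted when
rounding occurs. Samples shallower than the depth are dropped with a
warning rather than up-sampled, standard rarefaction practice.

## Community analytics

Bray–Curtis dissimilarity and Shannon diversity (natural-log units) are
implemented directly from their definitions and cross-checked in the test
suite against scipy's independent implementations. Complete-linkage
clustering delegates to `scipy.cluster.hierarchy`; dendrograms serialize to
Newick with branch length = parent height − child height. The
structure-function comparison pools all within-group sample pairs, pairing
the taxonomic with the functional Bray–Curtis value per pair, and reports
the Pearson correlation and fitted line per group; groups with fewer than
three samples (fewer than two pairs) are skipped.

Dissimilarities are intended to be computed on rarefied tables; the
functions accept any non-negative table, so relative abundances can be
passed where depth was equalized elsewhere. Bespoke re-implementations of
standard inferential statistics (two-way ANOVA, PERMANOVA, NMDS) are
deliberately out of scope; count tables export to TSV for external tools.

## Synthetic data: what it emulates and what it does not

Real inputs are multi-gigabyte MG-RAST stage files against era-specific
reference annotations, so the test bed is synthetic. The generator
emulates the regime of gut-metagenome GH profiling: 30 domain families by
default with canonical lengths spanning 50–805 AA (805 = the longest GH
domain), proteins carrying 1–3 domains with probabilities 0.5/0.3/0.2
(multidomain architectures are common among glycoside hydrolases), 40 AA
linkers and flanks, reads with a 33 AA subject-space footprint (a fully
aligned ~100 nt read), and a configurable fraction of reads agglomerated
into clusters (default 20%, multiplicities 2–5).

Read placement is **constructive**: exactly `round(target_in_fraction ×
n_reads)` reads are placed fully inside a uniformly chosen envelope and the
rest fully inside linkers/flanks, both with margins that make ground truth
unambiguous at the default cutoff (a fully contained 33 AA read exceeds the
20 AA cutoff by 13). Fraction-recovery tests are therefore exact, not
statistical. A separate boundary mode emits deliberate exact-20/21 AA
overlaps to pin the strict comparison, and a uniform-coverage mode places
reads uniformly over in-envelope residues — envelope chosen with
probability proportional to its residue count, then a uniform
full-containment window — so expected per-domain counts are proportional
to total envelope residues. (Choosing a window uniformly over all
envelopes instead would leave a residual (L−32)/L trend after
normalization; residue-proportional choice is what uniform coverage
means.)

The generator does **not** emulate: sequencing error or partial/clipped
alignments (every read aligns full-length), compositional correlation
between domains, variable read lengths, chimeric or frameshifted reads, or
hits to proteins absent from the RAT. Passing tests therefore demonstrate
the correctness of the interval logic, counting, normalization and
subsampling — not robustness to alignment noise, which lives upstream in
the similarity search.

## Numerical and interface choices

* Intervals are 1-based inclusive throughout (HMMER envelope convention);
  reversed subject intervals in similarity files are normalized to
  (min, max) with the orientation flagged, not rejected.
* The RAT serialization is two TSVs (4-column envelopes + 2-column
  lengths); a 5-column single-file variant is split on load. Duplicate
  envelope rows are deduplicated with a warning; an envelope whose family
  lacks a length entry is a hard load error.
* All stochastic operations (generation, rarefaction) take an explicit
  seed or numpy Generator; identical configuration and seed give
  byte-identical fixture files.
* Degenerate inputs are defined, not crashed on: zero-variance columns in
  the length-bias diagnostic report r = 0 with a `degenerate` flag; an
  empty localization summary reports NaN with a warning; an all-zero pair
  is a Bray–Curtis error (the index is undefined there).

## Problem sizes in tests and the acceptance report

The verification suite runs the full pipeline at 10,000 reads for
ground-truth recovery (exact 40% in-domain fraction), 100,000
uniform-coverage reads for the length-bias diagnostic with 50 seeded
replicates of the post-normalization significance test, 200 seeded draws
for the rarefaction-expectation check, and 1,000 random interval pairs
against a brute-force residue-set oracle. These sizes make the Monte-Carlo
checks decisive (3-standard-error bands) while keeping a full run around a
minute on one CPU.

## Known limitations

* The localizer is O(hits × envelopes-per-protein) in pure Python; at the
  scale of full MG-RAST projects (10⁶–10⁷ hits) a run takes minutes, not
  seconds. The per-sample design keeps memory flat.
* The `fetch` helper addresses the MG-RAST download API by accession and
  stage name; stage-file naming on the server has changed across pipeline
  versions and may need the configurable base URL or file id adjusted.
* Normalized-then-rarefied counts are not integers of reads; they are
  length-corrected pseudo-counts, and diversity metrics on them inherit
  that interpretation.
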