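"""Synthetic fixtures: reference tables, similarity files, and ground truth.

Real inputs for this pipeline are multi-gigabyte MG-RAST stage files tied
to era-specific reference annotations, so every module is exercised against
synthetic data with known ground truth instead.  The generator emulates the
regime of gut-metagenome GH profiling:

* domain families with canonical lengths spanning ~50–805 AA (805 being
  the longest GH domain, GH70);
* proteins with mono- and multidomain architectures (a 1/2/3-domain mix,
  echoing the prevalence of multidomain glycoside hydrolases), envelopes
  separated by linkers;
* reads whose translated footprint (default 33 AA ≈ 100 nt) lands either
  fully inside a domain envelope or fully in linker/flank sequence, with
  margins wide enough that ground truth is unambiguous at the default
  overlap cutoff;
* cluster files agglomerating a configurable fraction of reads.

Placement is constructive: the number of in-domain reads equals
``round(target_in_fraction × n_reads)`` exactly (positions are random,
counts are not), so fraction-recovery tests are exact rather than
statistical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .localize import DEFAULT_CUTOFF_AA
from .mgrast import ClusterMap, SimilarityRecord, write_cluster, write_similarity
from .rat import RAT, DomainEnvelope, write_lengths, write_rat

__all__ = [
    "SynthConfig",
    "ReadTruth",
    "generate_rat",
    "generate_reads",
    "generate_uniform_coverage",
    "generate_boundary_reads",
    "write_fixture",
    "write_truth",
]


@dataclass
class SynthConfig:
    """Knobs for the synthetic data regime.

    ``domains_per_protein`` maps architecture size (1, 2 or 3 domains) to
    its probability.  ``read_span_aa`` is the subject-space footprint of a
    read; 33 AA corresponds to a fully aligned 100 nt read.  ``cutoff`` is
    the overlap cutoff the fixture must be unambiguous for: in/out reads
    keep a margin of at least ``cutoff + 5`` AA from the boundary.
    ``round_robin_domains`` deals domains to proteins cyclically instead of
    at random, giving every domain the same number of occurrences — the
    clean setting for length-bias diagnostics.
    """

    n_domains: int = 30
    length_range: tuple[int, int] = (50, 805)
    n_proteins: int = 100
    domains_per_protein: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    linker_length: int = 40
    n_reads: int = 1000
    read_span_aa: int = 33
    target_in_fraction: float = 0.4
    cluster_rate: float = 0.2
    multiplicity_range: tuple[int, int] = (2, 5)
    cutoff: int = DEFAULT_CUTOFF_AA
    round_robin_domains: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.target_in_fraction <= 1.0):
            raise ValueError("target_in_fraction must lie in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if self.read_span_aa < self.cutoff + 5:
            raise ValueError(
                f"read_span_aa={self.read_span_aa} too short: in-domain reads "
                f"need an overlap margin of cutoff+5={self.cutoff + 5} AA"
            )
        if self.length_range[0] < self.read_span_aa:
            raise ValueError(
                "shortest domain cannot fully contain a read: "
                f"length_range[0]={self.length_range[0]} < read span {self.read_span_aa}"
            )
        if self.linker_length < self.read_span_aa:
            raise ValueError(
                f"linker_length={self.linker_length} cannot fully contain a "
                f"read of span {self.read_span_aa}"
            )
        probs = self.domains_per_protein
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ValueError("domains_per_protein must be a probability distribution")


@dataclass(frozen=True, slots=True)
class ReadTruth:
    """Ground-truth label for one synthetic read."""

    query_id: str
    placement: str  # IN | OUT | BOUNDARY
    domain_id: str  # assigned domain when IN, else ""
    multiplicity: int = 1


def _md5_like(tag: str) -> str:
    return hashlib.md5(tag.encode()).hexdigest()


def generate_rat(config: SynthConfig) -> RAT:
    """Build a synthetic RAT: domain families with random canonical lengths
    and proteins with 1–3 envelopes separated by linkers.  Envelope spans
    equal the canonical length (full-length domain occurrences)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.length_range
    domain_ids = [f"DOM{i:03d}" for i in range(config.n_domains)]
    lengths = {d: int(rng.integers(lo, hi + 1)) for d in domain_ids}
    arch_sizes = sorted(config.domains_per_protein)
    arch_probs = [config.domains_per_protein[k] for k in arch_sizes]
    rat = RAT(lengths=dict(lengths))
    cursor = 0
    for i in range(config.n_proteins):
        md5 = _md5_like(f"protein-{config.seed}-{i}")
        k = int(rng.choice(arch_sizes, p=arch_probs))
        k = min(k, config.n_domains)
        if config.round_robin_domains:
            # deal domains out cyclically so occurrence counts are balanced
            chosen = [(cursor + j) % config.n_domains for j in range(k)]
            cursor = (cursor + k) % config.n_domains
        else:
            chosen = rng.choice(config.n_domains, size=k, replace=False)
        pos = config.linker_length + 1
        for di in chosen:
            d = domain_ids[int(di)]
            rat.add(DomainEnvelope(md5, d, pos, pos + lengths[d] - 1))
            pos += lengths[d] + config.linker_length
    rat.validate()
    return rat


def _all_envelopes(rat: RAT) -> list[DomainEnvelope]:
    return [e for envs in rat.envelopes.values() for e in envs]


def _linker_regions(rat: RAT, linker: int) -> list[tuple[str, int, int]]:
    """Inter-envelope and flank regions of each protein, each ``linker`` AA."""
    regions = []
    for md5, envs in rat.envelopes.items():
        bounds = sorted((e.env_start, e.env_end) for e in envs)
        regions.append((md5, bounds[0][0] - linker, bounds[0][0] - 1))
        for (_, e1), (s2, _) in zip(bounds, bounds[1:]):
            regions.append((md5, e1 + 1, s2 - 1))
        regions.append((md5, bounds[-1][1] + 1, bounds[-1][1] + linker))
    return regions


class _Filler:
    """Pre-drawn plausible m8 filler columns (identity, mismatches, e-value,
    bit score); never used by the localizer, so tests must not depend on
    their values."""

    def __init__(self, rng: np.random.Generator, n: int):
        self.identity = np.round(rng.uniform(80.0, 99.9, size=n), 1).tolist()
        self.mismatches = rng.integers(0, 4, size=n).tolist()
        self.e_value = (10.0 ** -rng.integers(5, 50, size=n).astype(float)).tolist()
        self.bit_score = np.round(rng.uniform(40.0, 200.0, size=n), 1).tolist()

    def record(self, i: int, query_id: str, md5: str, s_start: int, span: int
               ) -> SimilarityRecord:
        return SimilarityRecord(
            query_id=query_id,
            subject_md5=md5,
            pct_identity=self.identity[i],
            aln_length=span,
            mismatches=self.mismatches[i],
            gap_openings=0,
            q_start=1,
            q_end=span * 3,
            s_start=s_start,
            s_end=s_start + span - 1,
            e_value=self.e_value[i],
            bit_score=self.bit_score[i],
        )


def generate_reads(
    config: SynthConfig, rat: RAT
) -> tuple[list[SimilarityRecord], ClusterMap, list[ReadTruth]]:
    """Emit similarity records with constructive in/out placement plus a
    cluster map agglomerating ``cluster_rate`` of the reads."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    span = config.read_span_aa
    envelopes = _all_envelopes(rat)
    regions = [r for r in _linker_regions(rat, config.linker_length)
               if r[2] - r[1] + 1 >= span]
    if not envelopes or not regions:
        raise ValueError("RAT geometry cannot host both in- and out-of-domain reads")
    n_in = round(config.target_in_fraction * config.n_reads)
    records: list[SimilarityRecord] = []
    truths: list[ReadTruth] = []
    n_clustered = round(config.cluster_rate * config.n_reads)
    lo_m, hi_m = config.multiplicity_range
    members: dict[str, list[str]] = {}
    filler = _Filler(rng, config.n_reads)
    for i in range(config.n_reads):
        qid = f"read{i:06d}"
        if i < n_in:
            env = envelopes[int(rng.integers(len(envelopes)))]
            start = int(rng.integers(env.env_start, env.env_end - span + 2))
            records.append(filler.record(i, qid, env.md5, start, span))
            placement, domain = "IN", env.domain_id
        else:
            md5, r_start, r_end = regions[int(rng.integers(len(regions)))]
            start = int(rng.integers(r_start, r_end - span + 2))
            records.append(filler.record(i, qid, md5, start, span))
            placement, domain = "OUT", ""
        mult = 1
        if i < n_clustered:  # agglomerate the first cluster_rate fraction
            mult = int(rng.integers(lo_m, hi_m + 1))
            members[qid] = [f"{qid}.m{j}" for j in range(1, mult)]
        truths.append(ReadTruth(qid, placement, domain, mult))
    # shuffle record order so file order carries no signal
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truths = [truths[i] for i in order]
    return records, ClusterMap(members), truths


def generate_uniform_coverage(
    config: SynthConfig, rat: RAT
) -> tuple[list[SimilarityRecord], list[ReadTruth]]:
    """Reads uniform over in-envelope residues: an envelope is chosen with
    probability proportional to its residue count, then a start position
    uniform among the full-containment windows inside it.  Expected
    per-domain read counts are then proportional to the domain's total
    envelope residues — the regime where raw counts correlate with domain
    length and length-normalized counts do not."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    span = config.read_span_aa
    envelopes = _all_envelopes(rat)
    spans = np.array([e.span_aa for e in envelopes], dtype=float)
    if (spans < span).any():
        raise ValueError("every envelope must be able to contain a full read")
    weights = spans / spans.sum()
    idx = rng.choice(len(envelopes), size=config.n_reads, p=weights)
    # uniform start among full-containment windows, drawn vectorized
    env_starts = np.array([e.env_start for e in envelopes])
    n_windows = np.array([e.span_aa - span + 1 for e in envelopes])
    starts = (env_starts[idx]
              + (rng.random(config.n_reads) * n_windows[idx]).astype(np.int64))
    md5s = [e.md5 for e in envelopes]
    domains = [e.domain_id for e in envelopes]
    idx_l = idx.tolist()
    starts_l = starts.tolist()
    records: list[SimilarityRecord] = []
    truths: list[ReadTruth] = []
    filler = _Filler(rng, config.n_reads)
    for i in range(config.n_reads):
        ei = idx_l[i]
        qid = f"uread{i:06d}"
        records.append(filler.record(i, qid, md5s[ei], starts_l[i], span))
        truths.append(ReadTruth(qid, "IN", domains[ei]))
    return records, truths


def generate_boundary_reads(
    config: SynthConfig, rat: RAT
) -> tuple[list[SimilarityRecord], list[ReadTruth]]:
    """Deliberate edge cases: for each envelope, one read overlapping it by
    exactly ``cutoff`` AA and one by exactly ``cutoff + 1`` AA (hanging off
    the envelope's 3' edge into the linker).  Used to pin down the strict
    '>' comparison at the cutoff."""
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    span = config.read_span_aa
    envelopes = _all_envelopes(rat)
    filler = _Filler(rng, 2 * len(envelopes))
    records: list[SimilarityRecord] = []
    truths: list[ReadTruth] = []
    i = 0
    for env in envelopes:
        for ov in (config.cutoff, config.cutoff + 1):
            start = env.env_end - ov + 1
            if start < env.env_start:
                continue
            qid = f"bread{i:06d}"
            records.append(filler.record(i, qid, env.md5, start, span))
            truths.append(ReadTruth(qid, "BOUNDARY", env.domain_id))
            i += 1
    return records, truths


def write_truth(truths: Sequence[ReadTruth], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query_id\tplacement\tdomain\tmultiplicity\n")
        for t in truths:
            fh.write(f"{t.query_id}\t{t.placement}\t{t.domain_id}\t{t.multiplicity}\n")


def write_fixture(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture directory: rat.tsv, lengths.tsv,
    sample.650.tsv, sample.330.tsv, truth.tsv.  Byte-deterministic for a
    given config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rat = generate_rat(config)
    records, clusters, truths = generate_reads(config, rat)
    paths = {
        "rat": outdir / "rat.tsv",
        "lengths": outdir / "lengths.tsv",
        "sim": outdir / "sample.650.tsv",
        "cluster": outdir / "sample.330.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_rat(rat, paths["rat"])
    write_lengths(rat.lengths, paths["lengths"])
    write_similarity(records, paths["sim"])
    write_cluster(clusters, paths["cluster"])
    write_truth(truths, paths["truth"])
    return paths
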