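"""Parsers for MG-RAST pipeline stage files.

Two tabular stage outputs feed the localizer:

* the **"650" similarity file** — local-alignment hits of reads (or cluster
  representatives) against the M5nr protein database, in the 12-column
  BLAST tabular ("m8") layout with subject coordinates in amino-acid space;
* the **"330" sequence-agglomeration file** — which reads were collapsed
  under each representative before the similarity search, the source of
  per-hit multiplicities.

Both parsers accept '#' comment lines and transparently handle gzip
(MG-RAST delivers compressed stage files).  An optional fetcher downloads
stage files through the MG-RAST REST API; nothing else in the package
requires the network.
"""

from __future__ import annotations

import gzip
import io
import urllib.request
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "SimilarityRecord",
    "ClusterMap",
    "SimilarityParseError",
    "ClusterParseError",
    "parse_similarity",
    "read_similarity",
    "write_similarity",
    "parse_cluster",
    "read_cluster",
    "write_cluster",
    "best_hit_per_query",
    "fetch_mgrast",
]

MGRAST_BASE_URL = "https://api.mg-rast.org/download"
_STAGES = {"650": "650.superblat.expand.protein", "330": "330.cluster.aa90.mapping"}


class SimilarityParseError(ValueError):
    pass


class ClusterParseError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class SimilarityRecord:
    """One 12-column tabular local-alignment hit (m8 layout).

    Subject coordinates (``s_start``, ``s_end``) are 1-based inclusive
    amino-acid positions on the reference protein and are normalized so
    ``s_start <= s_end``; ``reverse_subject`` records whether the input
    interval was reversed.  These protein-space coordinates are the only
    geometry the domain localizer uses.
    """

    query_id: str
    subject_md5: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    reverse_subject: bool = False

    def __post_init__(self) -> None:
        if self.s_start < 1 or self.s_end < 1:
            raise ValueError("subject coordinates must be positive")
        if self.s_start > self.s_end:
            raise ValueError("s_start must be <= s_end after normalization")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


class ClusterMap:
    """Read-agglomeration multiplicities keyed by representative id.

    ``multiplicity(rep) = 1 + number of member reads`` collapsed under it
    (the representative is itself a read); any identifier absent from the
    file has multiplicity 1.
    """

    def __init__(self, members: dict[str, list[str]] | None = None):
        self._members: dict[str, list[str]] = members or {}

    def multiplicity(self, query_id: str) -> int:
        return 1 + len(self._members.get(query_id, ()))

    def members(self, query_id: str) -> list[str]:
        return list(self._members.get(query_id, ()))

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, query_id: str) -> bool:
        return query_id in self._members

    def representatives(self) -> Iterator[str]:
        return iter(self._members)


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed text file by magic bytes."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_similarity(stream: Iterable[str]) -> list[SimilarityRecord]:
    """Parse a "650" similarity stream into records.

    Reversed subject intervals (translated search on the minus frame) are
    normalized to ``(min, max)`` with the orientation flagged rather than
    rejected.
    """
    records: list[SimilarityRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise SimilarityParseError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
            )
        try:
            s_start, s_end = int(parts[8]), int(parts[9])
            reverse = s_start > s_end
            if reverse:
                s_start, s_end = s_end, s_start
            rec = SimilarityRecord(
                query_id=parts[0],
                subject_md5=parts[1],
                pct_identity=float(parts[2]),
                aln_length=int(parts[3]),
                mismatches=int(parts[4]),
                gap_openings=int(parts[5]),
                q_start=int(parts[6]),
                q_end=int(parts[7]),
                s_start=s_start,
                s_end=s_end,
                e_value=float(parts[10]),
                bit_score=float(parts[11]),
                reverse_subject=reverse,
            )
        except ValueError as exc:
            raise SimilarityParseError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def read_similarity(path: str | Path) -> list[SimilarityRecord]:
    with _open_text(path) as fh:
        return parse_similarity(fh)


def write_similarity(records: Iterable[SimilarityRecord], path: str | Path) -> None:
    """Write records back to the 12-column layout (round-trip inverse).

    Reversed-orientation records are re-emitted with swapped subject
    coordinates so that re-parsing reproduces the records exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            s1, s2 = (r.s_end, r.s_start) if r.reverse_subject else (r.s_start, r.s_end)
            fh.write(
                f"{r.query_id}\t{r.subject_md5}\t{r.pct_identity:g}\t{r.aln_length}"
                f"\t{r.mismatches}\t{r.gap_openings}\t{r.q_start}\t{r.q_end}"
                f"\t{s1}\t{s2}\t{r.e_value:g}\t{r.bit_score:g}\n"
            )


def parse_cluster(stream: Iterable[str]) -> ClusterMap:
    """Parse a "330" agglomeration stream.

    Layout per line: cluster id, representative id, comma-joined member ids,
    optional comma-joined percent identities.
    """
    members: dict[str, list[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ClusterParseError(
                f"line {lineno}: expected >=3 tab-separated columns, got {len(parts)}"
            )
        rep = parts[1]
        if rep in members:
            raise ClusterParseError(
                f"line {lineno}: duplicate representative {rep!r}"
            )
        member_field = parts[2].strip()
        members[rep] = member_field.split(",") if member_field else []
    return ClusterMap(members)


def read_cluster(path: str | Path) -> ClusterMap:
    with _open_text(path) as fh:
        return parse_cluster(fh)


def write_cluster(clusters: ClusterMap, path: str | Path, prefix: str = "aa90") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, rep in enumerate(clusters.representatives()):
            mem = clusters.members(rep)
            ids = ",".join(mem)
            pct = ",".join("97.0" for _ in mem)
            fh.write(f"{prefix}_{i}\t{rep}\t{ids}\t{pct}\n")


def _hit_order_key(r: SimilarityRecord):
    # total order: best bit score, then lowest e-value, then smallest md5,
    # then coordinates — makes selection invariant to input permutation
    return (-r.bit_score, r.e_value, r.subject_md5, r.s_start, r.s_end, r.q_start, r.q_end)


def best_hit_per_query(
    records: Iterable[SimilarityRecord],
) -> dict[str, SimilarityRecord]:
    """Keep one hit per query: highest bit score, ties by lower e-value,
    then lexicographically smallest subject md5 (a total order, so the
    result does not depend on input order)."""
    best: dict[str, SimilarityRecord] = {}
    for rec in records:
        cur = best.get(rec.query_id)
        if cur is None or _hit_order_key(rec) < _hit_order_key(cur):
            best[rec.query_id] = rec
    return best


def fetch_mgrast(
    accession: str,
    stage: str,
    dest: str | Path,
    base_url: str = MGRAST_BASE_URL,
    timeout: float = 120.0,
) -> Path:
    """Download a "650" or "330" stage file for an MG-RAST metagenome.

    Idempotent: if ``dest`` already exists and is non-empty the download is
    skipped.  Purely optional convenience — every analysis operation works
    from local files.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(_STAGES)}")
    if not accession.startswith(("mgm", "mgp")):
        raise ValueError(f"accession {accession!r} does not look like an MG-RAST id")
    dest = Path(dest)
    if dest.exists() and dest.stat().st_size > 0:
        return dest
    url = f"{base_url}/{accession}?file={_STAGES[stage]}"
    dest.parent.mkdir(parents=True, exist_ok=True)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp, open(dest, "wb") as out:
            while chunk := resp.read(1 << 20):
                out.write(chunk)
    except OSError as exc:
        raise RuntimeError(f"fetch of {accession} stage {stage} failed: {exc}") from exc
    return dest
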