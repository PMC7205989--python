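"""Reference annotation table (RAT): protein → domain envelope mapping.

The RAT is the lookup structure at the heart of domain-level short-read
annotation.  Each row maps a reference protein, identified by the MD5
checksum of its sequence (the M5nr convention), to one occurrence of a
protein domain with its HMM-envelope coordinates in amino acids.  A
companion table holds one canonical (Pfam model) length per domain family,
used later for length normalization of hit counts.

Coordinates are 1-based inclusive amino-acid positions, matching HMMER
envelope reporting.  A protein may carry several envelopes (multidomain
architectures) and envelopes of distinct families may overlap (subdomains
such as GH3C inside GH3 regions), so the container never assumes
disjointness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "DomainEnvelope",
    "RAT",
    "RatParseError",
    "read_rat",
    "read_lengths",
    "write_rat",
    "write_lengths",
    "load_gh_lengths",
]

RAT_HEADER = ("md5", "domain", "env_start", "env_end")
LENGTH_HEADER = ("domain", "length")


class RatParseError(ValueError):
    """Malformed RAT or length-table input; message carries the line number."""


@dataclass(frozen=True)
class DomainEnvelope:
    """One domain occurrence on one reference protein.

    Attributes
    ----------
    md5 : protein identifier (opaque hex digest string).
    domain_id : domain family label, e.g. ``"GH13"``, ``"GH3C"``, ``"CBM48"``.
    env_start, env_end : 1-based inclusive amino-acid envelope bounds.
    """

    md5: str
    domain_id: str
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"invalid envelope [{self.env_start}, {self.env_end}]: "
                "need 1 <= env_start <= env_end"
            )

    @property
    def span_aa(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass
class RAT:
    """Reference annotation table: envelopes indexed by protein MD5, plus
    canonical domain lengths.

    ``lengths`` must cover every domain_id used by an envelope; this is
    enforced by :meth:`validate` (called by :func:`read_rat`).
    """

    envelopes: dict[str, list[DomainEnvelope]] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def add(self, env: DomainEnvelope) -> None:
        self.envelopes.setdefault(env.md5, []).append(env)

    def envelopes_for(self, md5: str) -> list[DomainEnvelope]:
        """All envelopes on a protein; empty list if the md5 is unknown."""
        return self.envelopes.get(md5, [])

    def __contains__(self, md5: str) -> bool:
        return md5 in self.envelopes

    def __iter__(self) -> Iterator[DomainEnvelope]:
        for envs in self.envelopes.values():
            yield from envs

    @property
    def n_envelopes(self) -> int:
        return sum(len(v) for v in self.envelopes.values())

    def domain_length(self, domain_id: str) -> int:
        """Canonical (Pfam model) length of a domain family in amino acids."""
        try:
            return self.lengths[domain_id]
        except KeyError:
            raise KeyError(
                f"domain {domain_id!r} has no entry in the length table"
            ) from None

    def validate(self) -> None:
        """Hard error if any envelope's domain lacks a canonical length."""
        missing = sorted(
            {e.domain_id for e in self} - set(self.lengths)
        )
        if missing:
            raise RatParseError(
                "domains without a length-table entry: " + ", ".join(missing)
            )
        bad = [d for d, ln in self.lengths.items() if ln < 1]
        if bad:
            raise RatParseError(
                "non-positive canonical lengths for: " + ", ".join(sorted(bad))
            )


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise RatParseError(
            f"line {lineno}: non-numeric {what}: {token!r}"
        ) from None


def read_rat(
    path: str | Path,
    lengths_path: str | Path | None = None,
) -> RAT:
    """Load a RAT from its tab-delimited serialization.

    The canonical dialect is two files: a 4-column envelope table
    (``md5  domain  env_start  env_end``) and a 2-column length table
    (``domain  length``).  A single-file 5-column variant with a trailing
    ``length`` column is accepted and split on load; a 6th column (protein
    length) is tolerated and ignored.  Duplicate identical envelope rows
    are dropped with a warning.
    """
    path = Path(path)
    rat = RAT()
    seen: set[tuple[str, str, int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != RAT_HEADER:
            raise RatParseError(
                f"{path}: expected header starting with {RAT_HEADER}, got {header}"
            )
        inline_length = len(header) >= 5 and header[4] == "length"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise RatParseError(
                    f"line {lineno}: expected >=4 tab-separated fields, got {len(parts)}"
                )
            md5, domain_id = parts[0], parts[1]
            start = _parse_int(parts[2], "env_start", lineno)
            end = _parse_int(parts[3], "env_end", lineno)
            try:
                env = DomainEnvelope(md5, domain_id, start, end)
            except ValueError as exc:
                raise RatParseError(f"line {lineno}: {exc}") from None
            key = (md5, domain_id, start, end)
            if key in seen:
                warnings.warn(
                    f"{path} line {lineno}: duplicate envelope row {key} dropped",
                    stacklevel=2,
                )
                continue
            seen.add(key)
            rat.add(env)
            if inline_length:
                length = _parse_int(parts[4], "length", lineno)
                prev = rat.lengths.get(domain_id)
                if prev is not None and prev != length:
                    raise RatParseError(
                        f"line {lineno}: conflicting lengths for {domain_id}: "
                        f"{prev} vs {length}"
                    )
                rat.lengths[domain_id] = length
    if lengths_path is not None:
        rat.lengths.update(read_lengths(lengths_path))
    rat.validate()
    return rat


def read_lengths(path: str | Path) -> dict[str, int]:
    """Load a 2-column ``domain  length`` table."""
    lengths: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:2]) != LENGTH_HEADER:
            raise RatParseError(
                f"{path}: expected header {LENGTH_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise RatParseError(
                    f"line {lineno}: expected 2 fields, got {len(parts)}"
                )
            length = _parse_int(parts[1], "length", lineno)
            if length < 1:
                raise RatParseError(
                    f"line {lineno}: canonical length must be >= 1, got {length}"
                )
            lengths[parts[0]] = length
    return lengths


def write_rat(rat: RAT, path: str | Path, lengths_path: str | Path | None = None) -> None:
    """Serialize a RAT; inverse of :func:`read_rat` (field-identical round trip).

    Envelopes are written grouped by md5 in insertion order, preserving the
    per-protein envelope order, so two write passes of the same RAT are
    byte-identical.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RAT_HEADER) + "\n")
        for envs in rat.envelopes.values():
            for e in envs:
                fh.write(f"{e.md5}\t{e.domain_id}\t{e.env_start}\t{e.env_end}\n")
    if lengths_path is not None:
        write_lengths(rat.lengths, lengths_path)


def write_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(LENGTH_HEADER) + "\n")
        for domain_id in sorted(lengths):
            fh.write(f"{domain_id}\t{lengths[domain_id]}\n")


def load_gh_lengths() -> dict[str, int]:
    """Packaged glycoside-hydrolase reference lengths.

    Ships the canonical normalization reference for GH profiling: GH70 at
    805 amino acids, the longest GH domain in the published reference
    annotation table and hence the default length-normalization reference.
    Extend or replace with the length table distributed alongside your RAT.
    """
    ref = resources.files("metagenehunt.data").joinpath("gh_lengths.tsv")
    lengths: dict[str, int] = {}
    lines = ref.read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if line:
            domain_id, length = line.split("\t")
            lengths[domain_id] = int(length)
    return lengths
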