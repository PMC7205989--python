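"""From localization results to per-sample domain count tables.

Three steps turn localized hits into comparable profiles:

1. **expansion** — each IN_DOMAIN hit contributes the number of reads
   agglomerated under its query id (from the "330" cluster file), since
   similarity searching runs on cluster representatives;
2. **length normalization** — raw counts over-represent long domains
   (more residues, more chances for a read to land); each domain count is
   multiplied by ``reference_length / domain_length``, the reference being
   the longest domain considered (805 AA, GH70, for the canonical GH
   table), so the longest domain has factor exactly 1;
3. **rarefaction** — per-sample subsampling without replacement
   (multivariate hypergeometric) to a common depth, equalizing sampling
   effort before community comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .localize import Classification, LocalizationResult
from .mgrast import ClusterMap

__all__ = [
    "CountTable",
    "NormalizationSpec",
    "LengthBiasReport",
    "expand_counts",
    "normalize_counts",
    "rarefy",
    "length_bias_diagnostic",
]


@dataclass
class CountTable:
    """Sample × feature abundance matrix with a processing-stage tag.

    ``data`` is a pandas DataFrame (rows = samples, columns = features).
    ``kind`` tracks the stage: raw integer counts, real-valued normalized
    counts, or rarefied integer counts; transitions only move forward
    (raw → normalized → rarefied).
    """

    data: pd.DataFrame
    kind: str = "raw"

    _KINDS = ("raw", "normalized", "rarefied")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def row(self, sample: str) -> pd.Series:
        return self.data.loc[sample]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "raw") -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(df, kind=kind)

    @classmethod
    def concat(cls, tables: Sequence["CountTable"]) -> "CountTable":
        """Stack single-sample rows into one table (union of features,
        missing cells zero)."""
        kinds = {t.kind for t in tables}
        if len(kinds) != 1:
            raise ValueError(f"cannot concat mixed kinds {kinds}")
        df = pd.concat([t.data for t in tables]).fillna(0.0)
        return cls(df, kind=kinds.pop())


@dataclass
class NormalizationSpec:
    """Length-normalization parameters.

    ``reference_length`` defaults (when None) to the maximum canonical
    length among features present in the table — the longest identified
    domain; pass 805 explicitly for parity with the canonical GH table.
    """

    length_table: Mapping[str, int]
    reference_length: int | None = None

    def resolve_reference(self, features: Sequence[str]) -> int:
        if self.reference_length is not None:
            if self.reference_length <= 0:
                raise ValueError("reference_length must be positive")
            return self.reference_length
        present = [self.length_table[f] for f in features if f in self.length_table]
        if not present:
            raise ValueError("no feature has a length entry; cannot infer reference")
        return max(present)


def expand_counts(
    results: Iterable[LocalizationResult],
    clusters: ClusterMap,
    sample_id: str,
) -> CountTable:
    """Sum cluster multiplicities of IN_DOMAIN hits per assigned domain;
    negatives and unclassified hits contribute nothing."""
    counts: dict[str, int] = {}
    for res in results:
        if res.classification is not Classification.IN_DOMAIN:
            continue
        counts[res.assigned_domain] = (
            counts.get(res.assigned_domain, 0) + clusters.multiplicity(res.query_id)
        )
    df = pd.DataFrame([counts], index=[sample_id], dtype=float).fillna(0.0)
    df = df[sorted(df.columns)]
    return CountTable(df, kind="raw")


def normalize_counts(table: CountTable, spec: NormalizationSpec) -> CountTable:
    """Multiply each domain's counts by reference_length / domain_length."""
    if table.kind != "raw":
        raise ValueError(f"expected a raw table, got kind={table.kind!r}")
    missing = [f for f in table.features if f not in spec.length_table]
    if missing:
        raise KeyError(
            "features without a canonical length: " + ", ".join(sorted(missing))
        )
    ref = spec.resolve_reference(table.features)
    factors = np.array([ref / spec.length_table[f] for f in table.features])
    df = table.data.astype(float) * factors
    return CountTable(df, kind="normalized")


def _round_half_away(values: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; rarefaction needs plain half-away-from-zero
    return np.floor(values + 0.5)


def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator) -> CountTable:
    """Subsample each row to ``depth`` counts without replacement.

    Real-valued (normalized) tables are first rounded half-away-from-zero
    to integers.  Rows with fewer than ``depth`` total counts are dropped
    with a warning rather than up-sampled.  The draw is multivariate
    hypergeometric, reproducible under the same seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = table.data.to_numpy(dtype=float)
    ints = values.astype(np.int64)
    if not np.allclose(values, ints):
        warnings.warn(
            "non-integer counts rounded half-away-from-zero before rarefaction",
            stacklevel=2,
        )
        ints = _round_half_away(values).astype(np.int64)
    rows = []
    kept = []
    for sample, row in zip(table.samples, ints):
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < depth {depth} counts; dropped",
                stacklevel=2,
            )
            continue
        if total == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth, method="marginals"))
        kept.append(sample)
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(kept), len(table.features)),
        index=kept,
        columns=table.features,
    )
    return CountTable(df, kind="rarefied")


@dataclass
class LengthBiasReport:
    """Correlation of per-domain total counts with canonical domain length.

    Raw counts from uniform read coverage correlate positively with length;
    after length normalization the correlation should vanish.  ``degenerate``
    flags zero-variance inputs, where both coefficients are reported as 0.
    """

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_features: int
    degenerate: bool = False


def length_bias_diagnostic(
    table: CountTable, lengths: Mapping[str, int]
) -> LengthBiasReport:
    """Pearson and Spearman correlation of per-domain total count vs length."""
    feats = [f for f in table.features if f in lengths]
    if len(feats) < 3:
        raise ValueError("need at least 3 features with known lengths")
    totals = table.data[feats].sum(axis=0).to_numpy(dtype=float)
    lens = np.array([lengths[f] for f in feats], dtype=float)
    if np.ptp(totals) == 0 or np.ptp(lens) == 0:
        return LengthBiasReport(0.0, 1.0, 0.0, 1.0, len(feats), degenerate=True)
    pr = stats.pearsonr(totals, lens)
    sr = stats.spearmanr(totals, lens)
    return LengthBiasReport(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n_features=len(feats),
    )
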