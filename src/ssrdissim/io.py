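"""Domain types and readers/writers for multilocus SSR genotype data.

A microsatellite (SSR) locus is a tandem repeat of a short motif; alleles are
recorded as fragment sizes in base pairs and differ by integer multiples of
the repeat-unit length.  The containers here carry everything the
dissimilarity measures need: per-locus repeat-unit lengths and observed size
ranges, per-individual allele-size calls of arbitrary ploidy with
whole-locus missing data, and dense symmetric dissimilarity matrices.
"""

from __future__ import annotations

import io as _stdio
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ssrdissim")

#: Allele-size calls are rounded to whole repeat units; a residual larger
#: than this fraction of a repeat unit is treated as a genotyping error
#: rather than capillary drift.
ROUNDING_TOLERANCE = 0.25

#: Residuals below this are numerical noise and not worth a warning.
_EXACT_EPS = 1e-9

#: Measures whose values are confined to [0, 1].  MANMC variants are
#: unbounded (units: mutations per haploid genome copy).
BOUNDED_MEASURES = frozenset(
    {"IAM", "SMMc", "SMMc_sq", "SMMv", "SMMv_sq", "BRUVO"}
)

MEASURES = ("IAM", "SMMc", "SMMc_sq", "SMMv", "SMMv_sq", "MANMC", "MANMC_sq", "BRUVO")


class SSRError(Exception):
    """Base class for all package errors."""


class DataValidationError(SSRError):
    """Input data violates a structural or numerical precondition."""


class MonomorphicLocusError(SSRError):
    """A range-normalised quantity was requested at a locus with no size
    variation (maximum repeat difference zero)."""


class NoSharedLociError(SSRError):
    """A pair of individuals has no locus with data in both profiles."""


def round_repeat_units(value: float, *, context: str = "") -> int:
    """Round a repeat-count quantity to the nearest integer.

    Fragment sizes from capillary electrophoresis drift by a base pair or
    so; differences are therefore snapped to whole repeat units.  A residual
    above :data:`ROUNDING_TOLERANCE` repeat units is an error.
    """
    nearest = round(value)
    resid = abs(value - nearest)
    if resid > ROUNDING_TOLERANCE:
        raise DataValidationError(
            f"repeat-unit residual {resid:.3f} exceeds tolerance "
            f"{ROUNDING_TOLERANCE}{' (' + context + ')' if context else ''}"
        )
    if resid > _EXACT_EPS:
        logger.warning(
            "off-ladder allele difference %.4f rounded to %d%s",
            value, nearest, f" ({context})" if context else "",
        )
    return int(nearest)


@dataclass(frozen=True)
class LocusDef:
    """Per-locus metadata.

    Parameters
    ----------
    locus_id : str
        Text label.
    ltr : int
        Length of the tandem-repeat unit in nucleotides (>= 1).
    size_min, size_max : float
        Smallest / largest allele size (bp) observed at this locus across
        the dataset.  All range-normalised allele distances divide by the
        repeat-count span derived from these.
    """

    locus_id: str
    ltr: int
    size_min: float
    size_max: float
    delta_max: int = field(init=False)

    def __post_init__(self) -> None:
        if self.ltr < 1:
            raise DataValidationError(f"locus {self.locus_id}: ltr must be >= 1")
        if self.size_max < self.size_min:
            raise DataValidationError(
                f"locus {self.locus_id}: size_max < size_min"
            )
        dm = round_repeat_units(
            (self.size_max - self.size_min) / self.ltr,
            context=f"locus {self.locus_id} size range",
        )
        object.__setattr__(self, "delta_max", dm)

    @property
    def is_monomorphic(self) -> bool:
        return self.delta_max == 0


#: Marker for a whole-locus missing call in an :class:`SSRProfile`.
MISSING = None


@dataclass(frozen=True)
class SSRProfile:
    """One individual's allele-size calls at every locus of a dataset.

    ``calls`` is parallel to the dataset's locus list; each entry is either
    a tuple of exactly ``ploidy`` allele sizes in bp (homozygotes repeat the
    same size) or ``None`` for a locus missing as a whole.
    """

    individual_id: str
    ploidy: int
    calls: tuple[tuple[float, ...] | None, ...]

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise DataValidationError(
                f"{self.individual_id}: ploidy must be >= 1"
            )
        norm = []
        for k, call in enumerate(self.calls):
            if call is None:
                norm.append(None)
                continue
            call = tuple(float(a) for a in call)
            if len(call) != self.ploidy:
                raise DataValidationError(
                    f"{self.individual_id}, locus index {k}: expected "
                    f"{self.ploidy} allele sizes, got {len(call)}"
                )
            if any(a <= 0 for a in call):
                raise DataValidationError(
                    f"{self.individual_id}, locus index {k}: allele sizes "
                    "must be positive"
                )
            norm.append(call)
        object.__setattr__(self, "calls", tuple(norm))

    def n_typed(self) -> int:
        """Number of non-missing loci."""
        return sum(c is not None for c in self.calls)


@dataclass
class Dataset:
    """An ordered set of loci and equally-ploid individuals typed at them.

    Locus size bounds (and hence each locus's maximum repeat-count
    difference) are always recomputed from the calls actually present, so
    adding individuals can only widen the per-locus ranges.
    """

    loci: list[LocusDef]
    individuals: list[SSRProfile]

    def __post_init__(self) -> None:
        if self.individuals:
            q = self.individuals[0].ploidy
            for ind in self.individuals:
                if ind.ploidy != q:
                    raise DataValidationError(
                        f"mixed ploidy: {ind.individual_id} has q={ind.ploidy}, "
                        f"expected {q}"
                    )
                if len(ind.calls) != len(self.loci):
                    raise DataValidationError(
                        f"{ind.individual_id}: {len(ind.calls)} loci, dataset "
                        f"has {len(self.loci)}"
                    )

    @property
    def ploidy(self) -> int:
        return self.individuals[0].ploidy

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def locus_index(self, locus_id: str) -> int:
        for k, loc in enumerate(self.loci):
            if loc.locus_id == locus_id:
                return k
        raise KeyError(locus_id)


def build_dataset(
    locus_ids: Sequence[str],
    ltrs: Sequence[int] | Mapping[str, int],
    ids: Sequence[str],
    calls: Sequence[Sequence[Sequence[float] | None]],
    ploidy: int,
) -> Dataset:
    """Assemble a :class:`Dataset` from in-memory calls, recomputing the
    per-locus size bounds from the data.

    ``calls[i][j]`` is individual *i*'s call at locus *j*: a sequence of
    ``ploidy`` sizes in bp, or ``None`` if missing.
    """
    if isinstance(ltrs, Mapping):
        ltr_list = []
        for lid in locus_ids:
            if lid not in ltrs:
                raise DataValidationError(
                    f"locus {lid!r} absent from locus table"
                )
            ltr_list.append(int(ltrs[lid]))
    else:
        ltr_list = [int(x) for x in ltrs]

    individuals = [
        SSRProfile(
            individual_id=str(iid),
            ploidy=ploidy,
            calls=tuple(
                None if c is None else tuple(float(a) for a in c) for c in row
            ),
        )
        for iid, row in zip(ids, calls, strict=True)
    ]

    loci = []
    for j, (lid, ltr) in enumerate(zip(locus_ids, ltr_list)):
        sizes = [a for ind in individuals if ind.calls[j] is not None
                 for a in ind.calls[j]]
        if not sizes:
            raise DataValidationError(
                f"locus {lid!r}: no non-missing calls in dataset"
            )
        loc = LocusDef(locus_id=str(lid), ltr=ltr,
                       size_min=min(sizes), size_max=max(sizes))
        # every call must sit on the locus ladder (within rounding)
        for ind in individuals:
            if ind.calls[j] is None:
                continue
            for a in ind.calls[j]:
                round_repeat_units(
                    (a - loc.size_min) / ltr,
                    context=f"{ind.individual_id} locus {lid}",
                )
        if loc.is_monomorphic:
            logger.warning(
                "locus %s is monomorphic (delta_max = 0); it will be "
                "excluded from range-normalised measures", lid,
            )
        loci.append(loc)
    return Dataset(loci=loci, individuals=individuals)


# ---------------------------------------------------------------------------
# Tabular readers

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_locus_table(path: str | Path) -> dict[str, int]:
    """Read a locus metadata table with columns ``locus_id,ltr``."""
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "locus_id" not in cols or "ltr" not in cols:
        raise DataValidationError(
            f"locus table {path}: need columns locus_id,ltr; "
            f"got {list(df.columns)}"
        )
    return {
        str(r[cols["locus_id"]]): int(r[cols["ltr"]])
        for _, r in df.iterrows()
    }


def read_dataset(genotype_table: str | Path, locus_table: str | Path) -> Dataset:
    """Read a genotype table plus locus table into a :class:`Dataset`.

    The genotype table has one row per individual: an ``individual_id``
    column followed by ``q`` columns per locus headed ``locusID.1`` ...
    ``locusID.q`` (a bare ``locusID`` column means haploid).  Empty cells or
    ``NA`` mark missing calls; a locus must be missing as a whole — partial
    calls at a locus are an error.
    """
    ltrs = read_locus_table(locus_table)
    df = _read_table(genotype_table)
    if df.shape[1] < 2:
        raise DataValidationError("genotype table needs id + allele columns")
    id_col = df.columns[0]

    # group allele columns by locus, preserving first-appearance order
    locus_cols: dict[str, list[str]] = {}
    for col in df.columns[1:]:
        lid = col.rsplit(".", 1)[0] if "." in col else col
        locus_cols.setdefault(lid, []).append(col)

    qs = {len(cols) for cols in locus_cols.values()}
    if len(qs) != 1:
        raise DataValidationError(
            f"inconsistent ploidy across loci: column counts {sorted(qs)}"
        )
    q = qs.pop()

    for lid in locus_cols:
        if lid not in ltrs:
            raise DataValidationError(
                f"locus {lid!r} absent from locus table"
            )

    def _parse_cell(v: str) -> float | None:
        v = v.strip()
        if v == "" or v.upper() in {"NA", "NAN"}:
            return None
        return float(v)

    ids = [str(v) for v in df[id_col]]
    calls: list[list[tuple[float, ...] | None]] = []
    for _, row in df.iterrows():
        row_calls: list[tuple[float, ...] | None] = []
        for lid, cols in locus_cols.items():
            vals = [_parse_cell(row[c]) for c in cols]
            n_missing = sum(v is None for v in vals)
            if n_missing == len(vals):
                row_calls.append(None)
            elif n_missing:
                raise DataValidationError(
                    f"{row[id_col]}, locus {lid}: partial call "
                    f"({len(vals) - n_missing}/{len(vals)} alleles); a locus "
                    "must be missing as a whole"
                )
            else:
                row_calls.append(tuple(vals))  # type: ignore[arg-type]
        calls.append(row_calls)

    return build_dataset(list(locus_cols), ltrs, ids, calls, ploidy=q)


def write_dataset(dataset: Dataset, genotype_path: str | Path,
                  locus_path: str | Path) -> None:
    """Write a dataset back to genotype + locus CSV tables."""
    q = dataset.ploidy
    cols = ["individual_id"]
    for loc in dataset.loci:
        cols += ([loc.locus_id] if q == 1
                 else [f"{loc.locus_id}.{i + 1}" for i in range(q)])
    rows = []
    for ind in dataset.individuals:
        row: list[str] = [ind.individual_id]
        for call in ind.calls:
            row += [""] * q if call is None else [f"{a:g}" for a in call]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(genotype_path, index=False)
    pd.DataFrame(
        {"locus_id": [l.locus_id for l in dataset.loci],
         "ltr": [l.ltr for l in dataset.loci]}
    ).to_csv(locus_path, index=False)


# ---------------------------------------------------------------------------
# Dissimilarity matrices

@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity matrix with measure provenance.

    ``n_shared[i, k]`` records how many loci entered the comparison of
    individuals *i* and *k* (after missing-data intersection and, for
    range-normalised measures, exclusion of monomorphic loci).
    """

    ids: list[str]
    values: np.ndarray
    measure: str
    n_shared: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise DataValidationError(
                f"matrix shape {v.shape} does not match {n} ids"
            )
        if not np.allclose(v, v.T, atol=1e-9):
            raise DataValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise DataValidationError("matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise DataValidationError("negative dissimilarities")
        if self.measure in BOUNDED_MEASURES and (v > 1 + 1e-9).any():
            raise DataValidationError(
                f"measure {self.measure} must lie in [0, 1]"
            )
        self.values = v
        if self.n_shared is not None:
            self.n_shared = np.asarray(self.n_shared, dtype=int)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        k = self.ids.index(pair[1])
        return float(self.values[i, k])


def write_matrix(m: DissimilarityMatrix, path: str | Path,
                 format: str = "csv", precision: int = 6) -> None:
    """Write a matrix as labelled CSV or square PHYLIP (relaxed labels)."""
    path = Path(path)
    fmt = f"%.{precision}f"
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("id," + ",".join(m.ids) + "\n")
            for i, lab in enumerate(m.ids):
                fh.write(lab + "," + ",".join(fmt % v for v in m.values[i]) + "\n")
    elif format == "phylip-square":
        with open(path, "w") as fh:
            fh.write(f"{m.n}\n")
            for i, lab in enumerate(m.ids):
                fh.write(lab + "  " + "  ".join(fmt % v for v in m.values[i]) + "\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path: str | Path, format: str = "csv",
                measure: str = "unknown") -> DissimilarityMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        ids = [str(x) for x in df.index]
        values = df.to_numpy(dtype=float)
    elif format == "phylip-square":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(ids) != n:
            raise DataValidationError(f"{path}: expected {n} rows, got {len(ids)}")
        values = np.array(rows, dtype=float)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return DissimilarityMatrix(ids=ids, values=values, measure=measure)
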