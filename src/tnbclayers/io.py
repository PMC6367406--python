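"""Data model and readers/writers for expression matrices, clinical tables and gene sets.

The canonical on-disk dialect for every table is TSV (UTF-8, tab-delimited,
``.`` decimal), matching GEO series-matrix style exports.  Gene identifiers
are symbols throughout; the probe-to-gene mapping is an explicit column of
the expression table, never inferred.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "MarkerConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "write_manifest",
]

#: Allowed values of :attr:`ExpressionMatrix.scale_flag`.
SCALE_FLAGS = ("raw", "log2", "centered")

# Clinical category dialects (Table-1 style coding).
_SIZE_LEVELS = ("T1", "gtT1")
_GRADE_LEVELS = ("G1_2", "G3")
_NODAL_LEVELS = ("N0", "N1")
_YESNO_LEVELS = ("yes", "no")
_RESPONSE_LEVELS = ("pCR", "RD")

_NA_TOKENS = {"", "NA", "na", "NaN", "nan", "None"}


class FormatError(ValueError):
    """Raised when an input file violates the accepted dialect."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Probes/genes x samples expression matrix.

    ``values[i, j]`` is the expression of probe ``probe_ids[i]`` (mapping to
    gene ``gene_ids[i]``) in sample ``sample_ids[j]``.  After probe
    collapsing each gene appears exactly once and ``probe_ids == gene_ids``
    is permitted.
    """

    probe_ids: list[str]
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    batch: list[str] | None = None
    scale_flag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        n_probes, n_samples = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2 or n_probes == 0 or n_samples == 0:
            raise FormatError("expression matrix must be non-empty and 2-dimensional")
        if len(self.probe_ids) != n_probes or len(self.gene_ids) != n_probes:
            raise FormatError("probe_ids/gene_ids length must match row count")
        if len(self.sample_ids) != n_samples:
            raise FormatError("sample_ids length must match column count")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise FormatError(f"duplicate sample ids: {sorted(dupes)}")
        if _duplicates(self.probe_ids):
            raise FormatError(f"duplicate probe ids: {sorted(_duplicates(self.probe_ids))}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at probe {self.probe_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        if self.scale_flag not in SCALE_FLAGS:
            raise FormatError(f"scale_flag must be one of {SCALE_FLAGS}")
        if self.batch is not None:
            if len(self.batch) != n_samples:
                raise FormatError("batch length must match sample count")
            self.batch = [str(b) for b in self.batch]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Genes/probes x samples DataFrame indexed by probe id."""
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def gene_frame(self) -> pd.DataFrame:
        """Values indexed by gene id; requires collapsed (unique) genes."""
        if _duplicates(self.gene_ids):
            raise FormatError("gene_frame requires collapsed probes (unique gene ids)")
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy_with(self, **kwargs) -> "ExpressionMatrix":
        fields = dataclasses.asdict(self)
        fields["values"] = self.values.copy()
        fields.update(kwargs)
        return ExpressionMatrix(**fields)


@dataclasses.dataclass
class ClinicalTable:
    """Per-sample clinical follow-up in the Table-1 dialect.

    ``rfs_time`` is relapse-free survival in months (time from surgery to
    distant relapse or last follow-up); ``event`` is 1 for distant relapse
    and 0 for censoring.  Categorical fields use NA for unknown.
    """

    frame: pd.DataFrame

    COLUMNS = (
        "sample_id",
        "rfs_time",
        "event",
        "size",
        "grade",
        "nodal",
        "adjuvant_chemo",
        "path_response",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id in clinical table: {dup}")
        t = f["rfs_time"]
        if (t.dropna() < 0).any():
            raise FormatError("negative rfs_time")
        ev = f["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise FormatError("event must be 0 or 1")
        if (f["event"].notna() & f["rfs_time"].isna()).any():
            raise FormatError("event defined without rfs_time")
        for col, levels in (
            ("size", _SIZE_LEVELS),
            ("grade", _GRADE_LEVELS),
            ("nodal", _NODAL_LEVELS),
            ("adjuvant_chemo", _YESNO_LEVELS),
            ("path_response", _RESPONSE_LEVELS),
        ):
            bad = f[col].dropna()[~f[col].dropna().isin(levels)]
            if len(bad):
                raise FormatError(f"unknown {col} token: {bad.iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclasses.dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    term_ids: list[str]
    term_names: list[str]
    genes: list[list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if not (len(self.term_ids) == len(self.term_names) == len(self.genes)):
            raise FormatError("term_ids, term_names and genes must align")
        if _duplicates(self.term_ids):
            raise FormatError(f"duplicate term ids: {sorted(_duplicates(self.term_ids))}")
        for tid, gl in zip(self.term_ids, self.genes):
            if len(gl) == 0:
                raise FormatError(f"term {tid} has no genes")

    def __len__(self) -> int:
        return len(self.term_ids)

    def as_dict(self) -> dict[str, list[str]]:
        return dict(zip(self.term_ids, self.genes))


#: Roles a marker list (and hence a metanode) can take.
MARKER_ROLES = ("luminal", "basal", "claudin", "immune")

#: Claudin markers that must be present in any claudin marker list.
DEFAULT_CLAUDIN_MARKERS = ("CLDN3", "CLDN4", "CLDN7")


@dataclasses.dataclass
class MarkerConfig:
    """Role -> marker gene list used to tag metanodes and the claudin node."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        for role in self.markers:
            if role not in MARKER_ROLES:
                raise FormatError(f"unknown marker role {role!r}; allowed: {MARKER_ROLES}")
        if "claudin" in self.markers:
            missing = [g for g in DEFAULT_CLAUDIN_MARKERS if g not in self.markers["claudin"]]
            if missing:
                raise FormatError(f"claudin marker list must include {missing}")
        for role, genes in self.markers.items():
            if len(genes) == 0:
                raise FormatError(f"marker role {role} has an empty gene list")

    def __getitem__(self, role: str) -> list[str]:
        return self.markers[role]

    def roles(self) -> list[str]:
        return list(self.markers)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    orientation: str = "genes_by_samples",
    batch_row: str | None = None,
    scale_flag: str = "raw",
) -> ExpressionMatrix:
    """Read an expression TSV.

    Layout (``orientation='genes_by_samples'``, the default): a header of
    sample ids, a ``probe_id`` column, a ``gene_id`` column, then numeric
    cells.  ``orientation='samples_by_genes'`` accepts the transposed
    layout — a ``sample_id`` first column and a header of gene ids (probe
    ids then equal gene ids).  If ``batch_row`` names a row of the file
    (matched against probe_id), that row is popped and used as per-sample
    batch labels; a ``__batch__`` row is picked up automatically.
    """
    path = Path(path)
    if orientation == "samples_by_genes":
        return _read_expression_transposed(path, scale_flag)
    if orientation != "genes_by_samples":
        raise FormatError("orientation must be 'genes_by_samples' or 'samples_by_genes'")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] != ["probe_id", "gene_id"]:
        raise FormatError(f"{path}: first two columns must be probe_id and gene_id")
    sample_ids = header[2:]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise FormatError(f"{path}: duplicate sample id in header: {sorted(dupes)}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] < 3:
        raise FormatError(f"{path}: empty or malformed expression matrix")

    batch = None
    if batch_row is None and (raw["probe_id"] == "__batch__").any():
        batch_row = "__batch__"  # our own writer's sidecar row
    if batch_row is not None:
        mask = raw["probe_id"] == batch_row
        if not mask.any():
            raise FormatError(f"{path}: batch row {batch_row!r} not found")
        batch = [str(v) for v in raw.loc[mask].iloc[0, 2:]]
        raw = raw.loc[~mask]

    probe_ids = raw["probe_id"].tolist()
    gene_ids = raw["gene_id"].tolist()
    cells = raw.iloc[:, 2:].mask(raw.iloc[:, 2:].isin(_NA_TOKENS))
    try:
        values = cells.astype(float).to_numpy()
    except ValueError:
        for i, row in enumerate(cells.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at line {i + 2}, "
                        f"sample {sample_ids[j]}"
                    ) from None
        raise
    # probes with any missing value are unusable downstream (correlations,
    # k-means assume complete data): drop them, loudly
    incomplete = ~np.isfinite(values).all(axis=1)
    if incomplete.any():
        dropped = [probe_ids[i] for i in np.flatnonzero(incomplete)]
        logging.getLogger(__name__).warning(
            "%s: dropping %d probe(s) with missing values (e.g. %s)",
            path, len(dropped), dropped[:5],
        )
        keep = ~incomplete
        values = values[keep]
        probe_ids = [p for p, k in zip(probe_ids, keep) if k]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        if values.shape[0] == 0:
            raise FormatError(f"{path}: every probe has missing values")
    return ExpressionMatrix(
        probe_ids, gene_ids, sample_ids, values, batch=batch, scale_flag=scale_flag
    )


def _read_expression_transposed(path: Path, scale_flag: str) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "sample_id":
        raise FormatError(f"{path}: transposed layout needs a 'sample_id' first column")
    gene_ids = header[1:]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise FormatError(f"{path}: duplicate gene id in header: {sorted(dupes)}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise FormatError(f"{path}: empty or malformed expression matrix")
    sample_ids = raw["sample_id"].tolist()
    dupes = _duplicates(sample_ids)
    if dupes:
        raise FormatError(f"{path}: duplicate sample id: {sorted(dupes)}")
    try:
        values = raw.iloc[:, 1:].astype(float).to_numpy().T
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(
        list(gene_ids), list(gene_ids), sample_ids, values, scale_flag=scale_flag
    )


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV; full float precision, batch as a sidecar row."""
    path = Path(path)
    frame = pd.DataFrame(m.values, columns=m.sample_ids)
    frame.insert(0, "gene_id", m.gene_ids)
    frame.insert(0, "probe_id", m.probe_ids)
    if m.batch is not None:
        batch_row = pd.DataFrame(
            [["__batch__", "__batch__", *m.batch]], columns=frame.columns
        )
        frame = pd.concat([batch_row, frame], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, tab-separated genes (deduplicated)."""
    path = Path(path)
    term_ids, term_names, genes = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            term_ids.append(fields[0])
            term_names.append(fields[1])
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g and g not in seen:
                    seen[g] = None
            if not seen:
                raise FormatError(f"{path}: line {lineno} lists no genes")
            genes.append(list(seen))
    if not term_ids:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(term_ids, term_names, genes, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, name, gl in zip(collection.term_ids, collection.term_names, collection.genes):
            fh.write("\t".join([tid, name, *gl]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV in the Table-1 dialect; '', 'NA' and variants map to NA."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ClinicalTable.COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    frame = raw.mask(raw.isin(_NA_TOKENS))
    frame["rfs_time"] = pd.to_numeric(frame["rfs_time"], errors="raise")
    frame["event"] = pd.to_numeric(frame["event"], errors="raise")
    return ClinicalTable(frame)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run-manifest (seed, parameters, stage dimensions...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _duplicates(items: Sequence) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
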