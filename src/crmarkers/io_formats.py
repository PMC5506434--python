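"""Readers, writers and probe-level collapse for the pipeline's external formats.

The pipeline consumes gene-level log2 expression matrices (tab-delimited,
genes in rows, samples in columns) together with a per-sample metadata table
(sample_id, strain, tissue, group, replicate), gene-set collections in GMT
format, and qPCR Ct plates in CSV (see :mod:`crmarkers.crm_screen`). All
expression values are treated as log2 scale throughout; the readers never
transform. Gene symbols are case-preserved and matched case-sensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

META_COLUMNS = ("sample_id", "strain", "tissue", "group", "replicate")


@dataclass
class ExpressionStudy:
    """A log2 expression matrix with aligned per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index: gene symbol), samples in columns, finite
        log2 signal intensities.
    samples : pandas.DataFrame
        Indexed by sample_id, columns ``strain``, ``tissue``, ``group``,
        ``replicate``. Row order matches the column order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols in expression matrix: {dups[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns of values do not match samples index (order matters)")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample_ids in metadata")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        missing = [c for c in ("strain", "tissue", "group") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_tissue(self, tissue: str) -> "ExpressionStudy":
        keep = self.samples.index[self.samples["tissue"] == tissue]
        if len(keep) == 0:
            raise ValueError(f"no samples with tissue {tissue!r}")
        return ExpressionStudy(self.values[keep], self.samples.loc[keep])


@dataclass
class GeneSetCollection:
    """Named gene sets: ``set_id -> (description, members)`` with members deduplicated."""

    sets: Dict[str, Tuple[str, Tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: Dict[str, Tuple[str, Tuple[str, ...]]] = {}
        for set_id, (desc, members) in self.sets.items():
            seen: Dict[str, None] = {}
            for m in members:
                seen.setdefault(m, None)
            cleaned[set_id] = (desc, tuple(seen))
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> Tuple[str, ...]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def intersect_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(
            {
                sid: (desc, tuple(g for g in members if g in uni))
                for sid, (desc, members) in self.sets.items()
            }
        )


def read_expression_study(matrix_path, meta_path) -> ExpressionStudy:
    """Read a tab-delimited expression matrix and its sample metadata table.

    The matrix has gene/probe IDs in the first column and a header row of
    sample IDs; metadata is tab-delimited with columns sample_id, strain,
    tissue, group, replicate. Samples are matched by sample_id and the
    column order of the matrix is preserved.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.index[coerced.isna() & values[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric expression value in column {col!r}, row {row!r} of {matrix_path}"
            )
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata file {meta_path} missing columns {missing_cols}")
    meta = meta.set_index("sample_id")
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")
    return ExpressionStudy(values, meta.loc[list(values.columns)])


def write_expression_study(study: ExpressionStudy, matrix_path, meta_path) -> None:
    study.values.to_csv(matrix_path, sep="\t", index_label="gene")
    study.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        meta_path, sep="\t", index=False
    )


def collapse_probesets(values: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes with no gene symbol or flagged ambiguous are dropped. For a gene
    measured by several probe sets, exactly the probe with the largest mean
    signal intensity across all supplied arrays is kept (ties broken by the
    lexicographically smallest probe_id, so the result is order-independent).
    Every output row is one input probe row verbatim, re-keyed by gene symbol.

    Parameters
    ----------
    values : pandas.DataFrame
        Probe-level matrix, rows keyed by probe_id.
    annot : pandas.DataFrame
        Columns ``probe_id``, ``gene_symbol`` (may be null), ``ambiguous`` (bool).
    """
    annot = annot.copy()
    if annot["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_ids in annotation")
    annot = annot.set_index("probe_id")
    keep = annot.index[annot["gene_symbol"].notna() & ~annot["ambiguous"].astype(bool)]
    keep = [p for p in keep if p in values.index]
    if not keep:
        raise ValueError("no probes left after filtering unannotated/ambiguous probe sets")
    sub = values.loc[keep]
    means = sub.mean(axis=1)
    best: Dict[str, str] = {}
    for probe in sorted(keep):  # lexicographic scan makes the tie-break explicit
        gene = annot.at[probe, "gene_symbol"]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    chosen = pd.Index(best.values())
    out = values.loc[chosen].copy()
    out.index = pd.Index(best.keys(), name="gene")
    return out.sort_index()


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``set_id TAB description TAB member...`` per line."""
    sets: Dict[str, Tuple[str, Tuple[str, ...]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            set_id, desc, *members = fields
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set_id {set_id!r}")
            sets[set_id] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> List[Path]:
    """Write a mapping of name -> DataFrame as TSV files under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=table.index.name is not None)
        written.append(p)
    return written
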