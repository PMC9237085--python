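"""Cross-dataset derivation of directional signatures and ortholog mapping.

A driver-specific signature is built by intersecting differential-expression
results from several model datasets: a gene enters the signature only when it
is significant in every dataset with the same sign of log2 fold change, and
its direction is that shared sign. Significant genes with conflicting signs
are excluded and reported. Mouse-model signatures are then translated to
human symbols through a user-supplied ortholog table (no live database
queries, for reproducibility).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .io import DirectionalSignature, ExpressionMatrix, normalize_symbol


@dataclass
class DETable:
    """One dataset's differential-expression results.

    Columns: ``gene``, ``log2fc``, ``padj`` and optionally ``significant``.
    When a ``significant`` column is present it overrides the padj/lfc
    thresholds for that dataset (useful when the source analysis published
    its own call set).
    """

    dataset_label: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = {"gene", "log2fc", "padj"} - set(df.columns)
        if missing:
            raise FormatError(
                f"DE table {self.dataset_label!r} missing columns: {sorted(missing)}"
            )
        df["gene"] = df["gene"].astype(str)
        norm = df["gene"].map(normalize_symbol)
        if norm.duplicated().any():
            raise FormatError(
                f"DE table {self.dataset_label!r}: duplicate genes after case normalization"
            )
        df["log2fc"] = df["log2fc"].astype(float)
        df["padj"] = df["padj"].astype(float)
        if ((df["padj"] < 0) | (df["padj"] > 1)).any():
            raise FormatError(f"DE table {self.dataset_label!r}: padj outside [0, 1]")
        df["_norm"] = norm
        self.data = df

    def significant(self, padj_threshold: float, lfc_threshold: float) -> pd.DataFrame:
        """Rows passing the thresholds (or the table's own significance calls)."""
        df = self.data
        if "significant" in df.columns:
            mask = df["significant"].astype(bool)
        else:
            mask = (df["padj"] <= padj_threshold) & (
                df["log2fc"].abs() >= lfc_threshold
            )
        mask &= df["log2fc"] != 0
        return df.loc[mask]


def read_de_table(path: str | Path, dataset_label: str | None = None) -> DETable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return DETable(dataset_label or Path(path).stem, df)


@dataclass
class OrthologMap:
    """Source-to-target symbol pairs; may be one-to-many either way."""

    pairs: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        missing = {"source_gene", "target_gene"} - set(df.columns)
        if missing:
            raise FormatError(f"ortholog map missing columns: {sorted(missing)}")
        df["source_gene"] = df["source_gene"].astype(str)
        df["target_gene"] = df["target_gene"].astype(str)
        df["_src"] = df["source_gene"].map(normalize_symbol)
        df["_tgt"] = df["target_gene"].map(normalize_symbol)
        if df.duplicated(["_src", "_tgt"]).any():
            df = df.drop_duplicates(["_src", "_tgt"])
        self.pairs = df.reset_index(drop=True)

    def targets_of(self, gene: str) -> list[str]:
        nm = normalize_symbol(gene)
        return list(self.pairs.loc[self.pairs["_src"] == nm, "target_gene"])


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two columns")
    df = df.rename(columns={df.columns[0]: "source_gene", df.columns[1]: "target_gene"})
    return OrthologMap(df)


@dataclass
class DerivationResult:
    """Output of :func:`derive_shared_signature`: the signature plus a
    report of sign-conflicting genes and per-dataset significant counts."""

    signature: DirectionalSignature | None
    conflicts: list[str]
    n_significant: dict[str, int]

    def conflict_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.conflicts})


def derive_shared_signature(
    tables: list[DETable],
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    min_datasets: int | None = None,
    name: str = "shared_signature",
) -> DerivationResult:
    """Intersect concordant significant genes across DE tables.

    A gene is included iff it is significant (padj <= ``padj_threshold`` and
    |log2fc| >= ``lfc_threshold``) in at least ``min_datasets`` tables
    (default: all of them) with an identical sign of log2fc; the shared sign
    becomes its direction. Genes significant in enough datasets but with
    conflicting signs are excluded and listed in the conflict report.

    The result is invariant to table order and to row order within tables.
    """
    if len(tables) < 2:
        raise ValueError("derive_shared_signature needs at least 2 DE tables")
    if not (0 < padj_threshold <= 1):
        raise ValueError("padj_threshold must lie in (0, 1]")
    if lfc_threshold < 0 or not np.isfinite(lfc_threshold):
        raise ValueError("lfc_threshold must be finite and nonnegative")
    k = len(tables) if min_datasets is None else int(min_datasets)
    if not (2 <= k <= len(tables)):
        raise ValueError("min_datasets must lie in [2, number of tables]")

    per_gene_signs: dict[str, list[int]] = {}
    display_name: dict[str, str] = {}
    n_significant: dict[str, int] = {}
    for tab in tables:
        sig = tab.significant(padj_threshold, lfc_threshold)
        n_significant[tab.dataset_label] = len(sig)
        if sig.empty:
            warnings.warn(
                f"DE table {tab.dataset_label!r} has no significant genes",
                stacklevel=2,
            )
        for nm, gene, lfc in zip(sig["_norm"], sig["gene"], sig["log2fc"]):
            per_gene_signs.setdefault(nm, []).append(1 if lfc > 0 else -1)
            display_name.setdefault(nm, gene)

    entries: dict[str, int] = {}
    conflicts: list[str] = []
    for nm in sorted(per_gene_signs):
        signs = per_gene_signs[nm]
        if len(signs) < k:
            continue
        if len(set(signs)) == 1:
            entries[display_name[nm]] = signs[0]
        else:
            conflicts.append(display_name[nm])
    signature = DirectionalSignature(name=name, entries=entries) if entries else None
    if signature is None:
        warnings.warn("no shared concordant genes; signature is empty", stacklevel=2)
    return DerivationResult(signature=signature, conflicts=sorted(conflicts),
                            n_significant=n_significant)


@dataclass
class MappingResult:
    """Output of :func:`map_orthologs`: mapped signature plus reports."""

    signature: DirectionalSignature | None
    unmapped: list[str]
    conflicts: list[str]  # targets hit with both directions, dropped


def map_orthologs(
    sig: DirectionalSignature,
    omap: OrthologMap,
    policy: str = "keep_all",
) -> MappingResult:
    """Translate a signature through an ortholog table.

    Each source gene is replaced by its mapped target(s); under
    ``drop_ambiguous`` a source gene with more than one target is dropped.
    Unmapped source genes are dropped and reported. When two source genes
    map onto one target with conflicting directions the target is dropped
    and reported.
    """
    if policy not in ("keep_all", "drop_ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    if len(omap.pairs) == 0:
        raise ValueError("empty ortholog map")
    unmapped: list[str] = []
    target_dir: dict[str, int] = {}
    target_name: dict[str, str] = {}
    conflicted: set[str] = set()
    for gene, direction in sig.entries.items():
        targets = omap.targets_of(gene)
        if not targets:
            unmapped.append(gene)
            continue
        if policy == "drop_ambiguous" and len(targets) > 1:
            unmapped.append(gene)
            continue
        for tgt in targets:
            nt = normalize_symbol(tgt)
            if nt in target_dir and target_dir[nt] != direction:
                conflicted.add(nt)
            target_dir.setdefault(nt, direction)
            target_name.setdefault(nt, tgt)
    entries = {
        target_name[nt]: d for nt, d in target_dir.items() if nt not in conflicted
    }
    signature = (
        DirectionalSignature(name=f"{sig.name}_mapped", entries=entries)
        if entries
        else None
    )
    return MappingResult(
        signature=signature,
        unmapped=unmapped,
        conflicts=sorted(target_name[nt] for nt in conflicted),
    )


def signature_overlap_report(
    sig: DirectionalSignature, m: ExpressionMatrix
) -> dict[str, object]:
    """Counts of signature genes present/absent in a matrix, per direction."""
    matrix_genes = set(m.normalized_index())
    present_up = sum(1 for g in sig.up_genes if normalize_symbol(g) in matrix_genes)
    present_down = sum(1 for g in sig.down_genes if normalize_symbol(g) in matrix_genes)
    absent = [g for g in sig.genes if normalize_symbol(g) not in matrix_genes]
    return {
        "signature": sig.name,
        "size": len(sig),
        "present": present_up + present_down,
        "absent": len(absent),
        "present_up": present_up,
        "present_down": present_down,
        "absent_genes": absent,
    }
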