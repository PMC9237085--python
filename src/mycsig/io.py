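"""Expression, gene-set, signature and survival I/O plus preprocessing.

The canonical in-memory containers are thin wrappers around pandas objects:
an :class:`ExpressionMatrix` is a genes x samples DataFrame carrying a scale
flag (``raw``, ``log2`` or ``log2-centered``); gene sets and directional
signatures are small dataclasses; survival data is a DataFrame with
``time`` / ``event`` (and optionally ``group``) columns indexed by sample.

Two preprocessing transforms are provided: :func:`log2_transform`
(log2(x + pseudocount)) and :func:`median_center` (subtract each gene's
across-sample median), the standard preparation for correlation-based
signature scoring of bulk expression cohorts.

Gene symbols are matched case-insensitively throughout the package (mouse
``Tap1`` vs human ``TAP1``); original spellings are preserved for output.
"""
from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .version import __version__

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_CENTERED = "log2-centered"
_SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_CENTERED)


def normalize_symbol(gene: str) -> str:
    """Case-normalized form of a gene symbol used for matching."""
    return str(gene).strip().upper()


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifier and scale metadata.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by gene symbol, columns by sample identifier.
    scale : {"raw", "log2", "log2-centered"}
        Units of the values.
    """

    data: pd.DataFrame
    scale: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        norm = self.data.index.map(normalize_symbol)
        if norm.duplicated().any():
            dups = sorted(set(norm[norm.duplicated()]))
            raise FormatError(
                f"duplicate gene identifiers after case normalization: {dups[:5]}"
            )
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate sample identifiers")
        values = self.data.to_numpy(dtype=float, na_value=np.nan)
        if np.isinf(values).any():
            raise FormatError("expression values must be finite or missing (NaN)")
        if self.data.shape[0] and np.isnan(values).all(axis=1).any():
            bad = self.data.index[np.isnan(values).all(axis=1)]
            raise FormatError(f"gene rows entirely missing: {list(bad[:5])}")
        self.data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def normalized_index(self) -> pd.Index:
        return self.data.index.map(normalize_symbol)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Rows whose case-normalized symbol is in ``genes`` (normalized)."""
        wanted = {normalize_symbol(g) for g in genes}
        mask = self.normalized_index().isin(wanted)
        return ExpressionMatrix(self.data.loc[mask], scale=self.scale)

    def samples_by_genes(self) -> pd.DataFrame:
        """Transposed view (samples x genes) for estimator-style scorers."""
        return self.data.T


def _sniff_sep(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    raise FormatError("could not detect delimiter (expected tab or comma)")


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    scale: str = SCALE_RAW,
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The first column holds identifiers and the header row holds the other
    axis' identifiers. Lines starting with ``#`` are ignored. Duplicate gene
    rows (after case normalization) are collapsed by their mean on the
    current scale, with a warning; duplicate sample identifiers are an error.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    if len(lines) < 2:
        raise FormatError(f"{path}: no data rows below the header")
    sep = _sniff_sep(lines[0])
    header_ids = [f.strip() for f in lines[0].split(sep)[1:]]
    if orientation == "genes_in_rows" and len(set(header_ids)) != len(header_ids):
        # pandas silently mangles duplicate header fields, so check the raw line
        raise FormatError(f"{path}: duplicate sample identifiers in header")
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns")
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample identifiers")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression values ({exc})") from None
    norm = df.index.map(normalize_symbol)
    if norm.duplicated().any():
        n_dup = int(norm.duplicated().sum())
        warnings.warn(
            f"{path}: collapsed {n_dup} duplicate gene row(s) by mean",
            stacklevel=2,
        )
        first_name = {}
        for orig, nm in zip(df.index, norm):
            first_name.setdefault(nm, orig)
        df = df.groupby(norm, sort=False).mean()
        df.index = df.index.map(first_name.get)
    return ExpressionMatrix(df, scale=scale)


def _header_comment(**params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# mycsig {__version__} {kv}".rstrip()


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(kind="expression", scale=m.scale) + "\n")
        m.data.to_csv(fh, sep="\t", index_label="gene")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace values by ``log2(value + pseudocount)``.

    Requires ``scale == "raw"``. Default pseudocount of 1 suits raw
    counts/TPM; pass 0 only when all values are strictly positive.
    """
    if m.scale != SCALE_RAW:
        raise ValueError(f"log2_transform expects raw values, got scale={m.scale!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    shifted = m.values + pseudocount
    if np.nanmin(shifted) <= 0:
        raise ValueError(
            "nonpositive value after adding pseudocount; increase the pseudocount"
        )
    out = pd.DataFrame(np.log2(shifted), index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, scale=SCALE_LOG2)


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample median (idempotent).

    Requires log2-scale input; the result carries scale ``log2-centered``
    and every row has median 0 up to floating tolerance.
    """
    if m.scale == SCALE_RAW:
        raise ValueError("median_center expects log2-scale values; run log2_transform first")
    values = m.values
    n_obs = (~np.isnan(values)).sum(axis=1)
    if (n_obs < 1).any():
        raise ValueError("gene row with no observed values cannot be centered")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(values, axis=1, keepdims=True)
    out = pd.DataFrame(values - med, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, scale=SCALE_CENTERED)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Named, unordered collection of unique gene symbols."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        norm = [normalize_symbol(g) for g in self.genes]
        if len(set(norm)) != len(norm):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def normalized(self) -> set[str]:
        return {normalize_symbol(g) for g in self.genes}


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a Broad-dialect GMT file: name, description, then genes,
    tab-separated, one set per line. Within-set duplicates are removed
    with a warning."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        fields = [f for f in fields[:2]] + [f for f in fields[2:] if f.strip()]
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        seen: dict[str, str] = {}
        for g in genes:
            seen.setdefault(normalize_symbol(g), g)
        if len(seen) < len(genes):
            warnings.warn(
                f"{path}:{lineno}: removed {len(genes) - len(seen)} duplicate "
                f"gene(s) in set {name!r}",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, description=desc, genes=list(seen.values())))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Directional signatures
# ---------------------------------------------------------------------------

_DIRECTION_TOKENS = {"+1": 1, "1": 1, "UP": 1, "-1": -1, "DOWN": -1, "−1": -1}


@dataclass
class DirectionalSignature:
    """Ordered set of (gene, direction) pairs with direction in {+1, -1}.

    The direction vector encodes which genes an upstream driver (here, MYC)
    up- or down-regulates; per-sample scores are correlations of centered
    expression against this vector.
    """

    name: str
    entries: Mapping[str, int] | Sequence[tuple[str, int]]

    def __post_init__(self) -> None:
        if isinstance(self.entries, Mapping):
            pairs = list(self.entries.items())
        else:
            pairs = [(g, int(d)) for g, d in self.entries]
        if not pairs:
            raise FormatError(f"signature {self.name!r} is empty")
        entries: dict[str, int] = {}
        norm_seen: dict[str, str] = {}
        for gene, direction in pairs:
            if direction not in (1, -1):
                raise FormatError(
                    f"signature {self.name!r}: direction for {gene!r} must be +1 or -1"
                )
            nm = normalize_symbol(gene)
            if nm in norm_seen:
                raise FormatError(
                    f"signature {self.name!r}: duplicate gene {gene!r}"
                )
            norm_seen[nm] = gene
            entries[str(gene)] = int(direction)
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DirectionalSignature)
            and self.name == other.name
            and dict(self.entries) == dict(other.entries)
        )

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def direction_of(self, gene: str) -> int:
        return self.normalized_entries()[normalize_symbol(gene)]

    def normalized_entries(self) -> dict[str, int]:
        return {normalize_symbol(g): d for g, d in self.entries.items()}

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.entries.items() if d == 1]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.entries.items() if d == -1]

    def flipped(self) -> "DirectionalSignature":
        """Same genes with every direction negated."""
        return DirectionalSignature(
            name=f"{self.name}_flipped",
            entries={g: -d for g, d in self.entries.items()},
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.entries), "direction": list(self.entries.values())}
        )


def read_signature(path: str | Path, name: str | None = None) -> DirectionalSignature:
    """Read a two-column TSV (gene, direction).

    Accepted direction tokens: ``+1``, ``-1``, ``1``, ``up``, ``down``
    (case-insensitive). A duplicated gene with conflicting signs is a
    format error; an exact duplicate is dropped with a warning.
    """
    sig_name = name
    pairs: list[tuple[str, int]] = []
    seen: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("#"):
            if "signature=" in line and sig_name is None:
                sig_name = line.split("signature=", 1)[1].split()[0]
            continue
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected gene<TAB>direction")
        gene, token = fields[0].strip(), fields[1].strip().upper()
        if token in ("GENE", "DIRECTION") or (gene.lower(), token.lower()) == ("gene", "direction"):
            continue  # optional header row
        if token not in _DIRECTION_TOKENS:
            raise FormatError(f"{path}:{lineno}: unrecognized direction {fields[1]!r}")
        direction = _DIRECTION_TOKENS[token]
        nm = normalize_symbol(gene)
        if nm in seen:
            if seen[nm] != direction:
                raise FormatError(
                    f"{path}:{lineno}: gene {gene!r} repeated with conflicting signs"
                )
            warnings.warn(f"{path}:{lineno}: duplicate entry for {gene!r} dropped",
                          stacklevel=2)
            continue
        seen[nm] = direction
        pairs.append((gene, direction))
    if sig_name is None:
        sig_name = Path(path).stem
    return DirectionalSignature(name=sig_name, entries=pairs)


def write_signature(sig: DirectionalSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(kind="signature", signature=sig.name) + "\n")
        for gene, direction in sig.entries.items():
            fh.write(f"{gene}\t{'+1' if direction == 1 else '-1'}\n")


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event indicator and optional group label.

    ``event == 1`` marks an observed event (recurrence/death); ``event == 0``
    marks censoring at ``time``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise FormatError(f"survival table missing columns: {sorted(missing)}")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise FormatError("duplicate sample identifiers in survival table")
        df["time"] = df["time"].astype(float)
        if (df["time"] < 0).any() or not np.isfinite(df["time"]).all():
            raise FormatError("survival times must be finite and nonnegative")
        ev = df["event"].astype(float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise FormatError("event indicator must be 0 (censored) or 1 (event)")
        df["event"] = ev.astype(int)
        if "group" in df.columns:
            df["group"] = df["group"].astype(str)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def group(self) -> pd.Series | None:
        return self.data["group"] if "group" in self.data.columns else None

    def with_groups(self, labels: pd.Series) -> "SurvivalTable":
        """Attach/replace group labels, keeping only labelled samples."""
        common = self.data.index.intersection(labels.index)
        if len(common) < len(self.data):
            warnings.warn(
                f"dropping {len(self.data) - len(common)} sample(s) without a group label",
                stacklevel=2,
            )
        df = self.data.loc[common].copy()
        df["group"] = labels.loc[common].astype(str)
        return SurvivalTable(df)

    def __len__(self) -> int:
        return len(self.data)


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival TSV with columns ``sample``, ``time``, ``event``
    and optionally ``group``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise FormatError(f"{path}: empty survival table")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = None
    return SurvivalTable(df)


def write_survival(s: SurvivalTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(kind="survival") + "\n")
        s.data.to_csv(fh, sep="\t", index_label="sample")
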