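"""PCA of encoded sequence sets and head-to-head scheme comparison.

PCA here is the covariance (center-only) convention: columns are mean-centered
but not scaled to unit variance, because binary lattices contain constant
columns (high-order bits) for which unit-variance scaling is undefined.
Zero-variance columns are dropped and reported.  Eigenvectors follow a
deterministic sign convention — the largest-magnitude loading of each
component is made positive — so scores are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .aaindex import IndexTable
from .encoding import Alignment, EncodedMatrix, encode_set, extract_block
from .errors import DegenerateMatrixError


@dataclass
class PCAResult:
    """Scores, loadings and the full variance spectrum of a centered PCA.

    ``variance_fraction`` covers every non-trivial component (length
    ``min(n - 1, p_retained)``) and sums to 1; ``scores`` and ``loadings``
    are truncated to the requested number of components.
    """

    scores: np.ndarray  # n x K
    loadings: np.ndarray  # p_retained x K
    variance_fraction: np.ndarray  # full spectrum, sums to 1
    retained_columns: list[str]
    dropped_columns: list[str]
    n_components: int
    centered: bool = True
    scaled: bool = False

    def pc_variance_percent(self, k: int = 2) -> float:
        """Combined percentage of variance explained by the first ``k`` PCs."""
        return float(self.variance_fraction[:k].sum() * 100.0)


def run_pca(matrix, n_components: int | None = None, columns=None) -> PCAResult:
    """Covariance PCA of an :class:`EncodedMatrix` (or plain 2-D array).

    Columns are mean-centered; exactly-constant columns are dropped and
    listed.  The decomposition is the SVD of the centered matrix, equivalent
    to the eigendecomposition of the sample covariance of retained columns;
    variance fractions are eigenvalues over their total.
    """
    if isinstance(matrix, EncodedMatrix):
        X = matrix.matrix
        columns = matrix.columns
    else:
        X = np.asarray(matrix, dtype=float)
        if columns is None:
            columns = [f"c{j}" for j in range(X.shape[1])]
    if X.ndim != 2:
        raise ValueError("input must be 2-D")
    n, p = X.shape
    if n < 2:
        raise DegenerateMatrixError(f"PCA needs at least 2 rows, got {n}")
    variances = X.var(axis=0)
    keep = variances > 0.0
    dropped = [c for c, k in zip(columns, keep) if not k]
    retained = [c for c, k in zip(columns, keep) if k]
    if not retained:
        raise DegenerateMatrixError("all columns have zero variance")
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = min(n - 1, len(retained))
    s = s[:rank]
    Vt = Vt[:rank]
    U = U[:, :rank]
    eigvals = s**2 / (n - 1)
    frac = eigvals / eigvals.sum()
    K = rank if n_components is None else min(n_components, rank)
    # Sign convention: per component, make the largest-|loading| entry positive.
    V = Vt.T[:, :K]
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Xc @ V
    return PCAResult(
        scores=scores,
        loadings=V,
        variance_fraction=frac,
        retained_columns=retained,
        dropped_columns=dropped,
        n_components=K,
    )


# ---------------------------------------------------------------------------
# Scheme comparison

@dataclass
class SchemeSummary:
    pc12_percent: float
    family_centroids: dict[str, tuple[float, float]]
    dropped_columns: int


@dataclass
class ComparisonReport:
    """PC1+PC2 variance and family centroids for both coding schemes."""

    schemes: dict[str, SchemeSummary]
    block_length: int
    n_sequences: int

    def to_dict(self) -> dict:
        return {
            "block_length": self.block_length,
            "n_sequences": self.n_sequences,
            "schemes": {
                name: {
                    "pc1_pc2_variance_percent": s.pc12_percent,
                    "family_centroids": {
                        f: [c[0], c[1]] for f, c in s.family_centroids.items()
                    },
                    "zero_variance_columns_dropped": s.dropped_columns,
                }
                for name, s in self.schemes.items()
            },
        }


def _sorted_alignment(aln: Alignment) -> Alignment:
    return Alignment(sorted(aln.records, key=lambda r: r.id))


def compare_encodings(
    aln: Alignment, table: IndexTable, max_gap_fraction: float = 0.0
) -> ComparisonReport:
    """Compare property coding against the 8-bit binary baseline on one set.

    The alignment is reduced to its homologous block, encoded under both
    schemes, and each lattice is analysed by covariance PCA; the report gives
    the PC1+PC2 combined variance percentage and per-family score centroids
    for each scheme.  Records are sorted by id first, so the report does not
    depend on input order.
    """
    aln = _sorted_alignment(aln)
    block, _ = extract_block(aln, max_gap_fraction=max_gap_fraction)
    schemes: dict[str, SchemeSummary] = {}
    for scheme in ("bpp", "binary8"):
        enc = encode_set(block, scheme, table if scheme == "bpp" else None)
        pca = run_pca(enc, n_components=2)
        centroids: dict[str, tuple[float, float]] = {}
        fams = np.array([f if f is not None else "" for f in enc.families])
        for fam in sorted(set(fams)):
            if not fam:
                continue
            pts = pca.scores[fams == fam, :2]
            centroids[fam] = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        schemes[scheme] = SchemeSummary(
            pc12_percent=pca.pc_variance_percent(2),
            family_centroids=centroids,
            dropped_columns=len(pca.dropped_columns),
        )
    return ComparisonReport(
        schemes=schemes, block_length=block.length, n_sequences=block.n_sequences
    )


# ---------------------------------------------------------------------------
# Export

def export_scores(
    result: PCAResult,
    ids: list[str],
    families: list[str | None] | None = None,
    stream: IO[str] | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Score table (id, family, PC1..PCK) as TSV, optionally with a scatter plot."""
    K = result.scores.shape[1]
    df = pd.DataFrame(result.scores, columns=[f"PC{k + 1}" for k in range(K)])
    df.insert(0, "family", [f if f else "" for f in (families or [None] * len(ids))])
    df.insert(0, "id", ids)
    if stream is not None:
        df.to_csv(stream, sep="\t", index=False, lineterminator="\n")
    if plot_path is not None:
        _scatter(df, result, plot_path)
    return df


def _scatter(df: pd.DataFrame, result: PCAResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    fams = df["family"].fillna("")
    for fam in sorted(fams.unique()):
        sub = df[fams == fam]
        ax.scatter(sub["PC1"], sub["PC2"], s=14, label=fam or "unlabelled", alpha=0.75)
    v = result.variance_fraction
    ax.set_xlabel(f"PC1 ({v[0] * 100:.1f}%)")
    if len(v) > 1 and "PC2" in df:
        ax.set_ylabel(f"PC2 ({v[1] * 100:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
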