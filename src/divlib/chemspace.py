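"""Descriptor matrices and PCA -> t-SNE embedding with KMeans composition.

200 two-dimensional molecular descriptors per compound (names recorded so
runs are comparable), standardized before PCA; KMeans runs on the PCA space
rather than the 2-D t-SNE coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler

from divlib.core_io import CompoundSet

#: descriptors excluded for numerical pathology (Ipc overflows on large molecules)
_EXCLUDED_DESCRIPTORS = ("Ipc",)
DEFAULT_N_DESCRIPTORS = 200


def descriptor_names(n: int = DEFAULT_N_DESCRIPTORS) -> list[str]:
    names = [name for name, _ in Descriptors._descList if name not in _EXCLUDED_DESCRIPTORS]
    if len(names) < n:
        raise RuntimeError(f"only {len(names)} descriptors available, need {n}")
    return names[:n]


@dataclass
class DescriptorMatrix:
    values: pd.DataFrame  # rows id-aligned, columns named
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def descriptor_matrix(cs: CompoundSet, n_descriptors: int = DEFAULT_N_DESCRIPTORS) -> DescriptorMatrix:
    """Compute the descriptor matrix; one row per compound, deterministic.

    Non-finite entries are imputed with the column mean; constant or
    all-missing columns are dropped with a warning before downstream use.
    """
    names = descriptor_names(n_descriptors)
    fns = dict(Descriptors._descList)
    rows = []
    for r in cs.records:
        mol = r.mol()
        row = []
        for name in names:
            try:
                v = float(fns[name](mol))
            except Exception:
                v = np.nan
            row.append(v)
        rows.append(row)
    df = pd.DataFrame(rows, index=cs.ids(), columns=names, dtype=float)
    df = df.replace([np.inf, -np.inf], np.nan)
    all_missing = [c for c in df.columns if df[c].isna().all()]
    df = df.drop(columns=all_missing)
    df = df.fillna(df.mean())
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    df = df.drop(columns=constant)
    dropped = all_missing + constant
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant/all-missing descriptor columns: {dropped}")
    return DescriptorMatrix(values=df, dropped_columns=dropped)


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # columns x, y; index = compound ids
    pca_coords: np.ndarray = field(repr=False, default=None)
    library_labels: pd.Series = None
    cluster_labels: pd.Series = None
    parameters: dict = field(default_factory=dict)


def embed(
    m: DescriptorMatrix,
    pca_dims: int = 30,
    perplexity: float = 50,
    iterations: int = 15000,
    seed: int = 0,
    library_labels: pd.Series | None = None,
) -> EmbeddingResult:
    """Standardize -> PCA(pca_dims) -> t-SNE(2); reproducible for a seed."""
    n = len(m.values)
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} rows is too few for perplexity {perplexity} (need >= {int(3 * perplexity)}); "
            "reduce perplexity"
        )
    x = StandardScaler().fit_transform(m.values.to_numpy())
    dims = min(pca_dims, x.shape[1], n)
    pca = PCA(n_components=dims, random_state=seed)
    xp = pca.fit_transform(x)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(xp)
    if library_labels is None:
        library_labels = pd.Series(["all"] * n, index=m.ids)
    return EmbeddingResult(
        coords=pd.DataFrame(coords, index=m.ids, columns=["x", "y"]),
        pca_coords=xp,
        library_labels=library_labels.reindex(m.ids),
        parameters={
            "pca_dims": dims,
            "perplexity": perplexity,
            "iterations": iterations,
            "seed": seed,
        },
    )


def cluster_composition(e: EmbeddingResult, k: int = 8, seed: int = 0) -> pd.DataFrame:
    """KMeans on the PCA space; returns a (cluster, library) count table.

    Counts sum to the input size. Cluster labels are stored back on the
    embedding result.
    """
    n = len(e.coords)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} rows")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(e.pca_coords)
    e.cluster_labels = pd.Series(labels, index=e.coords.index, name="cluster")
    e.parameters["k"] = k
    table = (
        pd.DataFrame({"cluster": labels, "library": e.library_labels.to_numpy()})
        .groupby(["cluster", "library"])
        .size()
        .rename("count")
        .reset_index()
    )
    return table


def embedding_to_csv(e: EmbeddingResult, path) -> None:
    df = e.coords.copy()
    df.insert(0, "library", e.library_labels)
    if e.cluster_labels is not None:
        df["cluster"] = e.cluster_labels
    df.index.name = "id"
    df.to_csv(path)


def plot_embedding(e: EmbeddingResult, path) -> None:
    """Scatter colored by library with per-dimension histograms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 9), gridspec_kw={"height_ratios": [1, 3], "width_ratios": [3, 1]})
    ax = axes[1, 0]
    for lib in sorted(e.library_labels.unique()):
        mask = (e.library_labels == lib).to_numpy()
        ax.scatter(e.coords.x[mask], e.coords.y[mask], s=4, alpha=0.5, label=lib)
        axes[0, 0].hist(e.coords.x[mask], bins=50, alpha=0.5)
        axes[1, 1].hist(e.coords.y[mask], bins=50, alpha=0.5, orientation="horizontal")
    axes[0, 1].axis("off")
    ax.legend(markerscale=3, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
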