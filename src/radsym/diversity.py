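"""Alpha diversity, Bray-Curtis distances, PCoA and UPGMA clustering.

Shannon entropy is in nats; Simpson is reported as Gini-Simpson
(1 - sum p^2) by default with an inverse-Simpson variant; Chao1 uses
the classic bias-corrected singleton/doubleton estimator on integer
counts.  Ordination is classical scaling (PCoA) of the double-centred
squared-distance matrix; clustering is average-linkage UPGMA with a
deterministic smallest-label tie-break and ultrametric output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "shannon",
    "simpson",
    "chao1",
    "bray_curtis",
    "distance_matrix",
    "alpha_diversity_table",
    "pcoa",
    "PCoAResult",
    "upgma",
]


def _clean(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0]
    return p / total


def shannon(p) -> float:
    """Shannon entropy H = -sum p ln p (nats); zeros skipped."""
    q = _clean(p)
    return float(-(q * np.log(q)).sum())


def simpson(p, variant: str = "gini") -> float:
    """Simpson diversity: ``"gini"`` -> 1 - sum p^2, ``"inverse"`` -> 1/sum p^2."""
    q = _clean(p)
    d = float((q**2).sum())
    if variant == "gini":
        return 1.0 - d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)) on integer counts."""
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if np.any(np.mod(c, 1) != 0):
            raise ValueError(
                "chao1 needs integer counts; convert abundances to "
                "pseudo-counts (e.g. per-species read counts S_i) first"
            )
        c = c.astype(int)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(x,y) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share a taxon index")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def distance_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between the rows (samples)."""
    ids = list(abundance.index)
    X = abundance.to_numpy(dtype=float)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return pd.DataFrame(D, index=ids, columns=ids)


def alpha_diversity_table(
    abundance: pd.DataFrame, counts: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample Shannon, Simpson and (when counts given) Chao1.

    ``counts`` carries the integer per-species read counts S_i used as
    the Chao1 count proxy; without it the Chao1 column is NaN.
    """
    rows = {}
    for sid in abundance.index:
        p = abundance.loc[sid].to_numpy(dtype=float)
        row = {"shannon": shannon(p), "simpson": simpson(p)}
        if counts is not None and sid in counts.index:
            row["chao1"] = chao1(counts.loc[sid].to_numpy().astype(int))
        else:
            row["chao1"] = np.nan
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # samples x retained axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    negative_eigenvalues: np.ndarray


def pcoa(D: pd.DataFrame | np.ndarray, atol: float = 1e-8) -> PCoAResult:
    """Classical scaling of a distance matrix.

    Double-centres ``-0.5 * D**2``, eigendecomposes, orders axes by
    eigenvalue and drops axes with negative eigenvalues (reported in
    the result).  Coordinates are eigenvectors scaled by sqrt(lambda).
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        ids = [f"s{i}" for i in range(M.shape[0])]
    if M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(M - M.T).max() > 1e-8:
        raise ValueError("distance matrix is not symmetric")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (M**2) @ J
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > atol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"PC{i+1}" for i in range(pos.sum())]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -atol],
    )


def upgma(D: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> str:
    """Average-linkage agglomeration returning a rooted ultrametric newick.

    Each merge happens at the current minimum average distance; a
    cluster sits at height = merge distance / 2 and its branch length
    is that height minus the child's height.  Ties are broken by the
    lexicographically smallest (label_i, label_j) pair, which makes the
    output deterministic.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(M.shape[0])]
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if np.abs(M - M.T).max() > 1e-8:
        raise ValueError("distance matrix is not symmetric")

    # cluster state: id -> (newick, height, size, representative label)
    clusters = {i: (labels[i], 0.0, 1, labels[i]) for i in range(n)}
    dist = {(i, j): M[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]][3], clusters[kv[0][1]][3]))),
            ),
        )
        (a, b), d = best
        nwk_a, h_a, n_a, rep_a = clusters[a]
        nwk_b, h_b, n_b, rep_b = clusters[b]
        h = d / 2.0
        # children ordered by smallest leaf label for a stable newick
        kids = sorted([(rep_a, nwk_a, h_a), (rep_b, nwk_b, h_b)])
        nwk = (f"({kids[0][1]}:{h - kids[0][2]:.10g},"
               f"{kids[1][1]}:{h - kids[1][2]:.10g})")
        new = next_id
        next_id += 1
        for c in clusters:
            if c in (a, b):
                continue
            d_ac = dist[tuple(sorted((a, c)))]
            d_bc = dist[tuple(sorted((b, c)))]
            dist[(c, new) if c < new else (new, c)] = (
                (n_a * d_ac + n_b * d_bc) / (n_a + n_b)
            )
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        del clusters[a], clusters[b]
        clusters[new] = (nwk, h, n_a + n_b, min(rep_a, rep_b))
    (nwk, _, _, _), = clusters.values()
    return nwk + ";"
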