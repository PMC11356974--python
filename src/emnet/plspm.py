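"""Partial least-squares path modeling (PLS-PM) with bootstrap inference.

Latent variables are estimated from indicator blocks by the classical
Lohmoller/Wold alternating algorithm: outer approximation (latent = weighted
sum of its standardized indicators), inner approximation (scheme-weighted
sum of adjacent latents), and outer-weight update (mode A: covariance of
each indicator with the inner proxy), iterated to convergence.  Inner path
coefficients are then OLS regressions of each endogenous latent on its
predecessors; model quality is summarized by per-block R-squared,
communalities, and the global goodness of fit

    GoF = sqrt(mean communality x mean R^2).

Effect decomposition sums products of path coefficients over all directed
routes: ``total = direct + indirect`` for every ordered latent pair.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("emnet")

__all__ = ["PLSPathModel", "pca_axes", "bray_curtis", "default_path_spec",
           "fit_plspm", "effects_decomposition"]


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity of a samples x taxa count table."""
    X = table.to_numpy(dtype=float)
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    # per-axis convention: the largest-magnitude score is positive
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    return scores


def pca_axes(data: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """First ``k`` ordination axes of a data table (PCA) or a symmetric
    dissimilarity matrix (classical PCoA).

    Square symmetric inputs with a zero diagonal are treated as
    dissimilarities and double-centred (Gower); otherwise columns are
    centred and scores come from the SVD.  Axis signs follow the
    largest-magnitude-score-positive convention.
    """
    X = data.to_numpy(dtype=float)
    n = len(data)
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    is_square = X.shape[0] == X.shape[1] and list(data.index) == list(data.columns)
    if is_square:
        if not np.allclose(X, X.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(X), 0.0, atol=1e-10):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (X ** 2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        scores = np.zeros((n, k))
        for j in range(k):
            if vals[j] > 1e-12:
                scores[:, j] = vecs[:, j] * np.sqrt(vals[j])
    else:
        Xc = X - X.mean(axis=0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        scores = (U * s)[:, :k]
        if scores.shape[1] < k:
            scores = np.pad(scores, ((0, 0), (0, k - scores.shape[1])))
    scores = _fix_signs(scores)
    return pd.DataFrame(scores, index=data.index,
                        columns=[f"Axis{j + 1}" for j in range(k)])


def default_path_spec() -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """The study-shaped four-block inner model.

    plant (richness) -> abiotic (SOC, TN, LC, LP), biotic (Assort, Avgdist,
    Ceneig) -> EM diversity (alpha set + two Bray-Curtis PCoA axes +
    subnetwork topology incl. multi_net).
    """
    blocks = {
        "plant": ["plant_richness"],
        "abiotic": ["SOC", "TN", "LC", "LP"],
        "biotic": ["Assort", "Avgdist", "Ceneig"],
        "em": ["richness", "shannon", "simpson", "chao1", "ace",
               "beta_axis1", "beta_axis2",
               "node_num", "edge_num", "betweenness_centrality", "multi_net"],
    }
    paths = [("plant", "abiotic"), ("plant", "biotic"), ("plant", "em"),
             ("abiotic", "em"), ("biotic", "em")]
    return blocks, paths


def _toposort(latents: Sequence[str], paths: Sequence[tuple[str, str]]) -> list[str]:
    preds = {l: {a for a, b in paths if b == l} for l in latents}
    out, done = [], set()
    while len(out) < len(latents):
        ready = [l for l in latents if l not in done and preds[l] <= done]
        if not ready:
            raise ValueError("inner path model must be acyclic")
        for l in ready:
            out.append(l)
            done.add(l)
    return out


class PLSPathModel(BaseEstimator):
    """Sklearn-style PLS path model estimator.

    Parameters
    ----------
    blocks : mapping latent name -> list of indicator columns (each
        indicator in exactly one block).
    paths : directed (source, target) latent pairs; must be acyclic.
    scheme : inner weighting scheme, ``"path"`` (default), ``"centroid"``
        or ``"factorial"``.
    mode : outer estimation mode, ``"A"`` (reflective, default) or ``"B"``.
    tol, max_iter : outer-weight convergence controls.
    bootstrap_n : resamples for path-coefficient CIs (0 disables).
    seed : RNG seed for the bootstrap.

    Fitted attributes (trailing underscore): ``scores_``, ``outer_weights_``,
    ``loadings_``, ``communalities_``, ``path_coefficients_``,
    ``r_squared_``, ``gof_``, ``effects_``, ``boot_``.
    """

    def __init__(self, blocks: Mapping[str, Sequence[str]] | None = None,
                 paths: Sequence[tuple[str, str]] | None = None,
                 scheme: str = "path", mode: str = "A", tol: float = 1e-7,
                 max_iter: int = 300, bootstrap_n: int = 500, seed: int = 0):
        self.blocks = blocks
        self.paths = paths
        self.scheme = scheme
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter
        self.bootstrap_n = bootstrap_n
        self.seed = seed

    # -- core algorithm -------------------------------------------------
    def _weights_and_scores(self, Xz: dict[str, np.ndarray],
                            latents: list[str],
                            preds: dict[str, set], succs: dict[str, set]
                            ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        n = next(iter(Xz.values())).shape[0]
        w = {l: np.ones(Xz[l].shape[1]) for l in latents}

        def outer_scores(w):
            Y = np.column_stack([Xz[l] @ w[l] for l in latents])
            sd = Y.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            return (Y - Y.mean(axis=0)) / sd

        Y = outer_scores(w)
        for _ in range(self.max_iter):
            C = np.corrcoef(Y, rowvar=False)
            if C.ndim == 0:
                C = np.array([[1.0]])
            Z = np.zeros_like(Y)
            for j, l in enumerate(latents):
                e = np.zeros(len(latents))
                if self.scheme == "centroid":
                    for i, m in enumerate(latents):
                        if m in preds[l] or m in succs[l]:
                            e[i] = np.sign(C[j, i])
                elif self.scheme == "factorial":
                    for i, m in enumerate(latents):
                        if m in preds[l] or m in succs[l]:
                            e[i] = C[j, i]
                elif self.scheme == "path":
                    pl = [i for i, m in enumerate(latents) if m in preds[l]]
                    if pl:
                        coef, *_ = np.linalg.lstsq(Y[:, pl], Y[:, j],
                                                   rcond=None)
                        e[pl] = coef
                    for i, m in enumerate(latents):
                        if m in succs[l]:
                            e[i] = C[j, i]
                else:
                    raise ValueError(f"unknown scheme {self.scheme!r}")
                if not e.any():      # isolated latent: keep outer proxy
                    Z[:, j] = Y[:, j]
                else:
                    Z[:, j] = Y @ e
            w_new = {}
            for j, l in enumerate(latents):
                z = Z[:, j]
                zsd = z.std(ddof=1)
                z = (z - z.mean()) / (zsd if zsd > 0 else 1.0)
                if self.mode == "A":
                    wn = Xz[l].T @ z / (n - 1)
                elif self.mode == "B":
                    wn, *_ = np.linalg.lstsq(Xz[l], z, rcond=None)
                else:
                    raise ValueError(f"unknown mode {self.mode!r}")
                norm = np.linalg.norm(wn)
                if norm == 0:
                    raise RuntimeError(f"outer weights collapsed for {l}")
                wn = wn / norm
                if wn[np.argmax(np.abs(wn))] < 0:  # sign-stabilize iteration
                    wn = -wn
                w_new[l] = wn
            delta = max(np.max(np.abs(w_new[l] - w[l] / np.linalg.norm(w[l])))
                        for l in latents)
            w = w_new
            Y = outer_scores(w)
            if delta < self.tol:
                break
        else:
            raise RuntimeError(
                f"outer weights did not converge in {self.max_iter} "
                f"iterations (last change {delta:.2e})")
        return w, Y

    def _fit_once(self, X: pd.DataFrame):
        blocks = {l: list(cols) for l, cols in self.blocks.items()}
        latents = _toposort(list(blocks), self.paths or [])
        blocks = {l: blocks[l] for l in latents}
        preds = {l: {a for a, b in self.paths if b == l} for l in latents}
        succs = {l: {b for a, b in self.paths if a == l} for l in latents}

        Xz = {}
        for l, cols in blocks.items():
            sub = X[cols].to_numpy(dtype=float)
            sd = sub.std(axis=0, ddof=1)
            if (sd == 0).any():
                bad = [c for c, s in zip(cols, sd) if s == 0]
                raise ValueError(f"constant indicator(s): {bad}")
            Xz[l] = (sub - sub.mean(axis=0)) / sd

        w, Y = self._weights_and_scores(Xz, latents, preds, succs)

        # orient each latent so its largest-magnitude loading is positive
        loadings = {}
        for j, l in enumerate(latents):
            lo = Xz[l].T @ Y[:, j] / (len(X) - 1)
            if lo[np.argmax(np.abs(lo))] < 0:
                Y[:, j] = -Y[:, j]
                w[l] = -w[l]
                lo = -lo
            loadings[l] = lo

        path = pd.DataFrame(0.0, index=latents, columns=latents)
        r2 = {}
        for j, l in enumerate(latents):
            pl = [i for i, m in enumerate(latents) if m in preds[l]]
            if not pl:
                continue
            coef, *_ = np.linalg.lstsq(Y[:, pl], Y[:, j], rcond=None)
            for i, c in zip(pl, coef):
                path.loc[latents[i], l] = float(c)
            resid = Y[:, j] - Y[:, pl] @ coef
            r2[l] = 1.0 - resid.var(ddof=0) / Y[:, j].var(ddof=0)
        return latents, blocks, w, Y, loadings, path, r2

    # -- sklearn API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "PLSPathModel":
        if self.blocks is None or self.paths is None:
            raise ValueError("blocks and paths must be provided")
        seen: set[str] = set()
        for l, cols in self.blocks.items():
            overlap = seen & set(cols)
            if overlap:
                raise ValueError(f"indicators in multiple blocks: {overlap}")
            seen |= set(cols)
        missing = seen - set(X.columns)
        if missing:
            raise ValueError(f"indicator columns not in data: {sorted(missing)}")
        if X[sorted(seen)].isna().any().any():
            raise ValueError("missing values are not supported")
        largest = max(len(c) for c in self.blocks.values())
        if len(X) <= largest:
            logger.warning("n=%d <= largest block size %d; estimates will "
                           "be unstable", len(X), largest)

        latents, blocks, w, Y, loadings, path, r2 = self._fit_once(X)
        self.latents_ = latents
        self.n_samples_ = len(X)
        self.scores_ = pd.DataFrame(Y, index=X.index, columns=latents)
        self.outer_weights_ = {l: pd.Series(w[l], index=blocks[l])
                               for l in latents}
        self.loadings_ = {l: pd.Series(loadings[l], index=blocks[l])
                          for l in latents}
        self.communalities_ = {l: self.loadings_[l] ** 2 for l in latents}
        self.path_coefficients_ = path
        self.r_squared_ = pd.Series(r2)
        all_comm = np.concatenate(
            [self.communalities_[l].to_numpy() for l in latents])
        self.gof_ = float(np.sqrt(all_comm.mean() * self.r_squared_.mean())) \
            if len(r2) else float("nan")
        self.effects_ = effects_decomposition(path)

        if self.bootstrap_n:
            self.boot_ = self._bootstrap(X)
        else:
            self.boot_ = None
        return self

    def _bootstrap(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        n = len(X)
        draws = []
        attempts = 0
        while len(draws) < self.bootstrap_n and attempts < 4 * self.bootstrap_n:
            attempts += 1
            idx = rng.integers(0, n, size=n)
            try:
                *_, path_b, _ = self._fit_once(X.iloc[idx])
            except (ValueError, RuntimeError):
                continue  # degenerate resample (constant indicator etc.)
            draws.append(path_b)
        rows = []
        for a, b in self.paths:
            samples = np.array([d.loc[a, b] for d in draws])
            est = self.path_coefficients_.loc[a, b]
            lo, hi = np.percentile(samples, [2.5, 97.5])
            frac_pos = (samples > 0).mean()
            p = 2.0 * min(frac_pos, 1.0 - frac_pos)
            rows.append({"from": a, "to": b, "estimate": est,
                         "boot_mean": samples.mean(), "ci_low": lo,
                         "ci_high": hi, "p": min(max(p, 1.0 / len(samples)), 1.0),
                         "n_boot": len(samples)})
        return pd.DataFrame(rows)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Latent scores for new samples using the fitted outer weights."""
        if not hasattr(self, "scores_"):
            raise RuntimeError("model is not fitted")
        out = {}
        for l in self.latents_:
            w = self.outer_weights_[l]
            sub = X[list(w.index)].to_numpy(dtype=float)
            z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
            s = z @ w.to_numpy()
            out[l] = (s - s.mean()) / s.std(ddof=1)
        return pd.DataFrame(out, index=X.index)


def effects_decomposition(path: pd.DataFrame) -> pd.DataFrame:
    """Direct/indirect/total effects from a (lower-triangular) path matrix.

    The indirect effect between two latents is the sum over all directed
    routes of the product of path coefficients, excluding the direct edge;
    total = direct + indirect.  The path matrix is nilpotent for an acyclic
    model, so the geometric series of matrix powers terminates.
    """
    if hasattr(path, "path_coefficients_"):
        path = path.path_coefficients_
    D = path.to_numpy(dtype=float)
    k = D.shape[0]
    total = np.zeros_like(D)
    P = D.copy()
    for _ in range(k):
        total += P
        P = P @ D
        if not P.any():
            break
    rows = []
    names = list(path.index)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j or (D[i, j] == 0 and total[i, j] == 0):
                continue
            rows.append({"from": a, "to": b, "direct": D[i, j],
                         "indirect": total[i, j] - D[i, j],
                         "total": total[i, j]})
    return pd.DataFrame(rows, columns=["from", "to", "direct", "indirect",
                                       "total"])


def fit_plspm(data: pd.DataFrame, blocks=None, paths=None, seed: int = 0,
              **kwargs) -> PLSPathModel:
    """Functional wrapper over :class:`PLSPathModel`."""
    if blocks is None or paths is None:
        default_blocks, default_paths = default_path_spec()
        blocks = blocks or default_blocks
        paths = paths or default_paths
    return PLSPathModel(blocks=blocks, paths=paths, seed=seed,
                        **kwargs).fit(data)
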