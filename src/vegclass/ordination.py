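"""Correspondence analysis and detrended correspondence analysis (DCA),
with Ellenberg indicator values as supplementary variables.

Covers enter the ordination as ``b = x**p`` (default ``p = 0.5``).  The
first axis is the first correspondence-analysis axis; every further axis is
extracted by iterated reciprocal averaging, detrending the site scores
against all previously extracted axes at each iteration by the
segment-means method (the axis range is split into ``n_segments`` equal
segments — 26 by default — and the segment mean is subtracted).  No
nonlinear rescaling is applied, so axes are reported in the weighted
unit-variance scaling of the extraction, not in SD units.

Plot-level community-weighted means (CWM) of Ellenberg indicator values
(light L, temperature T, continentality K, moisture F, reaction R,
nutrients N) can be fitted onto the axes as supplementary arrows with a
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .releve_io import Releve, ReleveTable

__all__ = [
    "CAResult",
    "DCAResult",
    "SupplementaryFit",
    "OrdinationError",
    "ca",
    "community_matrix",
    "cwm_eiv",
    "cwm_table",
    "dca",
    "detrend_segments",
    "fit_supplementary",
    "load_eiv",
    "transform_cover",
]

EIV_INDICATORS = ("L", "T", "K", "F", "R", "N")


class OrdinationError(ValueError):
    pass


def community_matrix(table: ReleveTable) -> pd.DataFrame:
    """Plots x species matrix of percent covers (layer-combined), with
    all-zero rows and columns pruned."""
    species = sorted(table.taxa)
    col = {sp: j for j, sp in enumerate(species)}
    data = np.zeros((len(table), len(species)))
    for i, rel in enumerate(table):
        for taxon, cover in rel.species_covers().items():
            data[i, col[taxon]] = 100.0 * cover
    df = pd.DataFrame(data, index=table.plot_ids, columns=species)
    df = df.loc[df.sum(axis=1) > 0, df.sum(axis=0) > 0]
    return df


def transform_cover(matrix: pd.DataFrame | np.ndarray, p: float = 0.5):
    """Entrywise power transform ``b = x**p`` (zero stays zero)."""
    if p <= 0:
        raise OrdinationError("transform exponent must be positive")
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if (values < 0).any():
        raise OrdinationError("negative covers in community matrix")
    out = values**p
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class CAResult:
    eigenvalues: np.ndarray  # (k,)
    row_scores: pd.DataFrame  # plots x axes, standard coordinates
    col_scores: pd.DataFrame  # species x axes, standard coordinates


def _margins(X: np.ndarray):
    total = X.sum()
    if total <= 0:
        raise OrdinationError("community matrix has zero total")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise OrdinationError("community matrix has an all-zero row or column")
    return P, r, c


def ca(matrix: pd.DataFrame, n_axes: int = 4) -> CAResult:
    """Correspondence analysis by SVD of the standardized residual matrix.

    Row and column scores are standard coordinates (weighted mean 0,
    weighted sum of squares 1); they satisfy the transition formulas: the
    cover-weighted average of column scores equals ``sqrt(eigenvalue)``
    times the row scores.
    """
    X = matrix.to_numpy(dtype=float)
    P, r, c = _margins(X)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int((sigma > 1e-12).sum())
    if rank == 0:
        raise OrdinationError("degenerate community matrix (rank 0)")
    k = min(n_axes, rank)
    axes = [f"CA{i+1}" for i in range(k)]
    row = U[:, :k] / np.sqrt(r)[:, None]
    col = Vt[:k].T / np.sqrt(c)[:, None]
    return CAResult(
        eigenvalues=sigma[:k] ** 2,
        row_scores=pd.DataFrame(row, index=matrix.index, columns=axes),
        col_scores=pd.DataFrame(col, index=matrix.columns, columns=axes),
    )


def detrend_segments(
    primary: np.ndarray, target: np.ndarray, n_segments: int = 26
) -> np.ndarray:
    """Detrend *target* against *primary* by the segment-means method.

    The primary axis range is split into ``n_segments`` equal-width
    segments; within each, the mean of the target scores is subtracted.  A
    degenerate primary (zero range) collapses to one segment, i.e. global
    mean-centering.
    """
    primary = np.asarray(primary, float)
    target = np.asarray(target, float)
    lo, hi = primary.min(), primary.max()
    out = target.copy()
    if hi <= lo or n_segments < 2:
        return out - out.mean()
    edges = np.linspace(lo, hi, n_segments + 1)
    idx = np.clip(np.searchsorted(edges, primary, side="right") - 1, 0, n_segments - 1)
    for s in range(n_segments):
        mask = idx == s
        if mask.any():
            out[mask] -= out[mask].mean()
    return out


@dataclass
class DCAResult:
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame  # plots x axes
    species_scores: pd.DataFrame  # species x axes
    n_segments: int

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def dca(
    matrix: pd.DataFrame,
    n_axes: int = 4,
    n_segments: int = 26,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> DCAResult:
    """Detrended correspondence analysis.

    Axis 1 is the plain CA axis 1.  Each later axis is found by reciprocal
    averaging, detrending against all previously extracted axes at every
    iteration, started deterministically from the corresponding CA axis.
    Raises on non-convergence, naming the axis and iteration count.
    """
    X = matrix.to_numpy(dtype=float)
    base = ca(matrix, n_axes=n_axes)
    P, r, c = _margins(X)
    rowsum = X.sum(axis=1)
    colsum = X.sum(axis=0)

    site_axes = [base.row_scores.to_numpy()[:, 0]]
    spec_axes = [base.col_scores.to_numpy()[:, 0]]
    eigenvalues = [base.eigenvalues[0]]

    n_extract = min(n_axes, base.row_scores.shape[1])
    for ax in range(1, n_extract):
        y = base.row_scores.to_numpy()[:, ax].copy()
        norm = np.sqrt((r * y**2).sum())
        if norm <= 0:
            break
        y /= norm
        lam = 0.0
        for it in range(1, max_iter + 1):
            s = (X.T @ y) / colsum
            y2 = (X @ s) / rowsum
            for prev in site_axes:
                y2 = detrend_segments(prev, y2, n_segments)
            lam = np.sqrt((r * y2**2).sum())
            if lam <= 1e-14:
                y = y2
                break
            y_new = y2 / lam
            if (r * y_new * y).sum() < 0:
                y_new = -y_new
            delta = np.max(np.abs(y_new - y))
            y = y_new
            if delta < tol:
                break
        else:
            raise OrdinationError(
                f"axis {ax + 1} did not converge after {max_iter} iterations"
            )
        if lam <= 1e-14:
            break
        site_axes.append(y)
        spec_axes.append((X.T @ y) / colsum)
        eigenvalues.append(float(lam))

    axes = [f"DCA{i+1}" for i in range(len(site_axes))]
    return DCAResult(
        eigenvalues=np.array(eigenvalues),
        site_scores=pd.DataFrame(
            np.column_stack(site_axes), index=matrix.index, columns=axes
        ),
        species_scores=pd.DataFrame(
            np.column_stack(spec_axes), index=matrix.columns, columns=axes
        ),
        n_segments=n_segments,
    )


# --------------------------------------------------------------------------
# Ellenberg indicator values


def load_eiv(path: str | Path | None = None) -> pd.DataFrame:
    """Load an indicator-value table (species x L,T,K,F,R,N; blanks = NA).

    The packaged default (`eiv_synthetic.csv`) is a SYNTHETIC stand-in for
    the published indicator tables, which are not redistributable; its
    values are plausible for the species concerned but must not be cited as
    the published ones.
    """
    if path is None:
        with (resources.files("vegclass.data") / "eiv_synthetic.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    df = df.set_index("species")
    return df[list(EIV_INDICATORS)].astype(float)


def cwm_eiv(releve: Releve, eiv: pd.DataFrame, indicator: str) -> float | None:
    """Cover-weighted mean indicator value of one relevé.

    Species without a value are excluded from both sums; returns None when
    no species of the relevé has a value (undefined).
    """
    num = den = 0.0
    values = eiv[indicator]
    for taxon, cover in releve.species_covers().items():
        v = values.get(taxon)
        if v is not None and not np.isnan(v):
            num += cover * v
            den += cover
    return num / den if den > 0 else None


def cwm_table(
    table: ReleveTable,
    eiv: pd.DataFrame | None = None,
    indicators: Sequence[str] = EIV_INDICATORS,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-plot CWM (or unweighted mean) indicator values; NaN = undefined."""
    eiv = load_eiv() if eiv is None else eiv
    rows = {}
    for rel in table:
        covers = rel.species_covers()
        if not weighted:
            covers = {t: 1.0 for t in covers}
        row = {}
        for ind in indicators:
            values = eiv[ind]
            num = den = 0.0
            for taxon, cover in covers.items():
                v = values.get(taxon)
                if v is not None and not np.isnan(v):
                    num += cover * v
                    den += cover
            row[ind] = num / den if den > 0 else np.nan
        rows[rel.plot_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(indicators)]


@dataclass
class SupplementaryFit:
    """Per indicator: unit direction in axis space, r² and permutation p."""

    directions: pd.DataFrame  # indicators x axes
    r2: pd.Series
    p: pd.Series
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        out = self.directions.copy()
        out["r2"] = self.r2
        out["p"] = self.p
        return out


def fit_supplementary(
    result: DCAResult,
    plot_values: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> SupplementaryFit:
    """Fit supplementary variables onto ordination axes.

    Each indicator is regressed (least squares, with intercept) on the site
    scores over the plots where it is defined; the fitted direction is the
    unit coefficient vector, r² the squared multiple correlation, and p a
    permutation p-value (values permuted across plots).  Constant
    indicators get r² = 0, p = 1.
    """
    rng = np.random.default_rng(seed)
    scores = result.site_scores
    axes = list(scores.columns)
    directions, r2s, ps = {}, {}, {}
    for ind in plot_values.columns:
        y_all = plot_values[ind].reindex(scores.index)
        mask = y_all.notna().to_numpy()
        if mask.sum() < 3:
            raise OrdinationError(
                f"indicator {ind!r}: fewer than 3 plots with defined values"
            )
        A = scores.to_numpy()[mask]
        y = y_all.to_numpy(dtype=float)[mask]

        def _r2(yy: np.ndarray) -> tuple[float, np.ndarray]:
            ss_tot = ((yy - yy.mean()) ** 2).sum()
            if ss_tot <= 0:
                return 0.0, np.zeros(A.shape[1])
            M = np.column_stack([np.ones(len(yy)), A])
            beta, *_ = np.linalg.lstsq(M, yy, rcond=None)
            resid = yy - M @ beta
            return 1.0 - (resid**2).sum() / ss_tot, beta[1:]

        r2_obs, beta = _r2(y)
        norm = np.linalg.norm(beta)
        directions[ind] = beta / norm if norm > 0 else beta
        r2s[ind] = r2_obs
        if r2_obs == 0.0:
            ps[ind] = 1.0
        else:
            count = sum(
                1
                for _ in range(n_permutations)
                if _r2(rng.permutation(y))[0] >= r2_obs
            )
            ps[ind] = (1 + count) / (1 + n_permutations)
    return SupplementaryFit(
        directions=pd.DataFrame.from_dict(directions, orient="index", columns=axes),
        r2=pd.Series(r2s),
        p=pd.Series(ps),
        n_permutations=n_permutations,
    )
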