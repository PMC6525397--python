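"""Multivariate curve resolution by alternating least squares (MCR-ALS).

The bilinear model

    D = C S^T + E

decomposes a scans x ROIs intensity matrix D into N components, each a pair
of an elution (concentration) profile — a column of C — and a pure mass
spectrum — a row of S^T on the ROI m/z grid.  For a column-wise augmented
matrix the same model reads D_aug = C_aug S^T + E_aug: one spectrum per
component shared by all runs, one elution block per run, with no alignment
or peak-shape assumption on the elution side.

The factors are found by alternating exact non-negative least squares
(active-set NNLS per row/column), under the two constraints that suffice for
sparse LC-MS data: non-negativity of both factors and unit-norm rows of S^T
(the scale being absorbed into C).  Exact subproblem solves make the residual
norm — reported as lack of fit, lof = 100*sqrt(sum(E^2)/sum(D^2)) —
non-increasing across iterations; the loop stops when the relative change in
lof falls below ``tol`` or after ``max_iter`` iterations.

Initial spectra are picked by a purest-variable procedure: starting from the
observed spectrum (row of D) of largest norm, iteratively add the row most
dissimilar (largest angle) to the span of those already picked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .msio import ValidationError

__all__ = [
    "MCRModel",
    "initialize_spectra",
    "mcr_als",
    "lack_of_fit",
    "explained_variance",
    "select_components",
]


class NumericalError(RuntimeError):
    """Raised when an ALS subproblem cannot be solved (rank deficiency)."""


@dataclass
class MCRModel:
    """Fitted bilinear factorization.

    ``C`` is (rows of D) x N, ``S_T`` is N x J with unit-Euclidean-norm rows
    (a row may be identically zero if its component collapsed, in which case
    its index is listed in ``collapsed_components``).
    """

    C: np.ndarray
    S_T: np.ndarray
    n_components: int
    lof_percent: float
    evar_percent: float
    n_iter: int
    converged: bool
    boundaries: list[tuple[int, int]] | None = None
    sample_ids: list[str] | None = None
    init_method: str = "purest"
    seed: int | None = None
    lof_history: list[float] = field(default_factory=list)
    collapsed_components: list[int] = field(default_factory=list)
    mzroi: np.ndarray | None = None

    def reconstruction(self) -> np.ndarray:
        return self.C @ self.S_T

    def component_block(self, component: int, sample: int) -> np.ndarray:
        """Elution profile of one component within one sample's row block."""
        if self.boundaries is None:
            raise ValidationError("model carries no sample boundaries")
        a, b = self.boundaries[sample]
        return self.C[a:b, component]


def lack_of_fit(D: np.ndarray, C: np.ndarray, S_T: np.ndarray) -> float:
    """lof (%) = 100 * sqrt(sum(E^2) / sum(D^2)), E = D - C S^T."""
    D = np.asarray(D, dtype=float)
    ss_d = float(np.sum(D * D))
    if ss_d == 0:
        raise ValidationError("lack of fit undefined for an all-zero matrix")
    E = D - C @ S_T
    return 100.0 * float(np.sqrt(np.sum(E * E) / ss_d))


def explained_variance(D: np.ndarray, C: np.ndarray, S_T: np.ndarray) -> float:
    """evar (%) = 100 * (1 - sum(E^2)/sum(D^2)) = 100 - lof^2/100."""
    D = np.asarray(D, dtype=float)
    ss_d = float(np.sum(D * D))
    if ss_d == 0:
        raise ValidationError("explained variance undefined for an all-zero matrix")
    E = D - C @ S_T
    return 100.0 * (1.0 - float(np.sum(E * E)) / ss_d)


def initialize_spectra(D: np.ndarray, n: int, seed: int | None = None) -> np.ndarray:
    """Select ``n`` initial pure spectra as the purest observed rows of D.

    Deterministic: the first pick is the largest-norm row; each further pick
    maximizes the fraction of its norm orthogonal to the span of the rows
    already picked (i.e. the sine of its angle to that span).  ``seed`` is
    accepted for interface symmetry and provenance; the procedure itself has
    no random element.  Returned rows are unit-normalized.
    """
    D = np.asarray(D, dtype=float)
    m, j = D.shape
    if not 1 <= n <= min(m, j):
        raise ValidationError(
            f"n={n} outside valid component range 1..{min(m, j)}"
        )
    norms = np.linalg.norm(D, axis=1)
    if norms.max() == 0:
        raise ValidationError("cannot initialize from an all-zero matrix")
    picked = [int(np.argmax(norms))]
    basis = D[picked[0]] / norms[picked[0]]
    Q = basis[None, :]
    for _ in range(1, n):
        proj = D @ Q.T  # m x k
        resid_sq = norms**2 - np.sum(proj**2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            purity = np.where(norms > 0, np.sqrt(np.clip(resid_sq, 0, None)) / norms, 0)
        purity[picked] = -1.0
        nxt = int(np.argmax(purity))
        if purity[nxt] <= 1e-12:
            # span exhausted: rank of D below n
            raise ValidationError(
                f"matrix rank supports fewer than n={n} distinct spectra"
            )
        picked.append(nxt)
        r = D[nxt] - (D[nxt] @ Q.T) @ Q
        Q = np.vstack([Q, r / np.linalg.norm(r)])
    S0 = D[picked].astype(float)
    S0 /= np.linalg.norm(S0, axis=1, keepdims=True)
    return S0


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for every column b of B; returns one
    solution column per column of B."""
    n = A.shape[1]
    X = np.empty((n, B.shape[1]))
    try:
        for k in range(B.shape[1]):
            X[:, k], _ = nnls(A, B[:, k])
    except Exception as exc:  # noqa: BLE001 — scipy raises RuntimeError on no convergence
        raise NumericalError(
            "NNLS subproblem failed — likely rank deficiency; "
            "try fewer components"
        ) from exc
    return X


def mcr_als(
    D: np.ndarray,
    n: int,
    max_iter: int = 50,
    tol: float = 0.001,
    seed: int | None = None,
    init_S: np.ndarray | None = None,
    boundaries: list[tuple[int, int]] | None = None,
    sample_ids: list[str] | None = None,
    mzroi: np.ndarray | None = None,
) -> MCRModel:
    """Fit the bilinear model D = C S^T + E by alternating NNLS.

    Parameters
    ----------
    D:
        Non-negative data matrix (an msroi or augmented msroi_aug).
    n:
        Number of components; must not exceed min(D.shape).
    max_iter, tol:
        Stop after ``max_iter`` iterations or when the relative change of the
        lack of fit drops below ``tol`` (default 0.001 = 0.1%).
    init_S:
        Optional explicit initial spectra (n x J); default is the purest-row
        selection of :func:`initialize_spectra`.
    boundaries, sample_ids, mzroi:
        Carried through to the model for augmented inputs.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ValidationError("D must be a 2-D matrix")
    if np.min(D) < 0:
        raise ValidationError("D must be non-negative (run fill-in first)")
    m, j = D.shape
    if not 1 <= n <= min(m, j):
        raise ValidationError(f"n={n} outside valid component range 1..{min(m, j)}")

    S_T = initialize_spectra(D, n, seed) if init_S is None else np.asarray(init_S, float)
    if S_T.shape != (n, j):
        raise ValidationError(f"initial spectra shape {S_T.shape} != ({n}, {j})")

    lof_history: list[float] = []
    converged = False
    it = 0
    C = np.zeros((m, n))
    for it in range(1, max_iter + 1):
        # C-step: rows of D are independent NNLS problems in the fixed spectra
        C = _nnls_rows(S_T.T, D.T).T
        # S-step: columns of D are independent NNLS problems in the fixed C
        S_T = _nnls_rows(C, D)
        # normalize spectra rows, absorbing scale into C (evar-neutral)
        norms = np.linalg.norm(S_T, axis=1)
        nonzero = norms > 0
        S_T[nonzero] /= norms[nonzero, None]
        C[:, nonzero] *= norms[nonzero]

        lof = lack_of_fit(D, C, S_T)
        if lof_history and lof_history[-1] > 0:
            rel = abs(lof_history[-1] - lof) / lof_history[-1]
            lof_history.append(lof)
            if rel < tol:
                converged = True
                break
        else:
            lof_history.append(lof)
            if lof_history[-1] == 0.0:
                converged = True
                break

    lof = lof_history[-1]
    evar = 100.0 * (1.0 - (lof / 100.0) ** 2)
    col_max = C.max(axis=0) if m else np.zeros(n)
    scale = col_max.max() if n else 0.0
    collapsed = [
        int(k) for k in range(n) if scale > 0 and col_max[k] <= 1e-12 * scale
    ]
    return MCRModel(
        C=C,
        S_T=S_T,
        n_components=n,
        lof_percent=float(lof),
        evar_percent=float(evar),
        n_iter=it,
        converged=converged,
        boundaries=boundaries,
        sample_ids=sample_ids,
        init_method="purest" if init_S is None else "user",
        seed=seed,
        lof_history=lof_history,
        collapsed_components=collapsed,
        mzroi=None if mzroi is None else np.asarray(mzroi, dtype=float),
    )


def select_components(
    D: np.ndarray,
    n_grid,
    gain_threshold: float = 0.1,
    **fit_kwargs,
):
    """Fit a grid of component counts and suggest where evar gains level off.

    Returns ``(table, suggested_n, low_confidence)``: a DataFrame of
    (n, lof_percent, evar_percent, converged), the smallest n whose evar gain
    over the previous grid point falls below ``gain_threshold`` percentage
    points, and a flag set when no grid point shows such a plateau (e.g. pure
    noise) so the suggestion is just the last grid value.  The full table is
    returned so the final choice stays with the analyst.
    """
    n_grid = list(n_grid)
    if not n_grid:
        raise ValidationError("n_grid must be non-empty")
    rows = []
    for n in n_grid:
        model = mcr_als(D, n, **fit_kwargs)
        rows.append(
            {
                "n": n,
                "lof_percent": model.lof_percent,
                "evar_percent": model.evar_percent,
                "converged": model.converged,
            }
        )
    table = pd.DataFrame(rows)
    suggested = None
    for prev, cur in zip(rows[:-1], rows[1:]):
        if cur["evar_percent"] - prev["evar_percent"] < gain_threshold:
            suggested = prev["n"]
            break
    low_confidence = suggested is None
    if suggested is None:
        suggested = rows[-1]["n"]
    if len(rows) == 1:
        suggested, low_confidence = rows[0]["n"], False
    return table, suggested, low_confidence
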