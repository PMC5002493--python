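"""Closed-form branch-choice predictor for rigid particles in asymmetric
pinched flow fractionation.

In the pinched segment (width w0) a particle is pressed against the lower
sidewall, so its centre sits a radius D/2 away from the wall.  With NB
outlets, outlets 1..NB-1 sharing the flow fraction (1 - beta) equally and
outlet NB taking the fraction beta, the wall-adjacent band of width
w0 (1 - beta)/(NB - 1) feeds outlet 1, the next band outlet 2, and so on;
everything above w0 (1 - beta) feeds outlet NB.  The predicted branch is
the band containing D/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PredictionInput:
    D: float          # particle diameter (same length unit as w0)
    beta: float       # outlet-NB flux fraction, in (0, 1)
    w0: float = 30.0  # pinched-segment width
    NB: int = 4       # number of outlets

    def __post_init__(self):
        if self.D <= 0 or self.w0 <= 0:
            raise ValueError("D and w0 must be positive")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.NB < 2:
            raise ValueError("need at least two outlets")


def band_edges(beta: float, w0: float = 30.0, NB: int = 4) -> np.ndarray:
    """The NB-1 diameter thresholds separating the predicted branches:
    threshold N = 2 w0 (1 - beta) N/(NB - 1), strictly increasing in N and
    decreasing in beta."""
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    N = np.arange(1, NB)
    return 2.0 * w0 * (1.0 - beta) * N / (NB - 1)


def predict_branch(inp: PredictionInput, edge_tol: float = 1e-9
                   ) -> tuple[int, bool]:
    """Predicted exit branch for a rigid particle.

    Returns (N, on_edge).  Bands are half-open [lower, upper) in D/2 with
    branch NB for D/2 >= w0 (1 - beta); the literal inequalities of the
    band rule are strict on both sides, leaving edge values unassigned,
    so the on_edge flag marks particles sitting within ``edge_tol`` (in
    diameter units) of a threshold, where the prediction is ambiguous.
    """
    if inp.D / 2.0 >= inp.w0:
        raise ValueError(
            f"particle diameter {inp.D} does not fit the pinched "
            f"segment of width {inp.w0}")
    edges = band_edges(inp.beta, inp.w0, inp.NB)
    N = 1 + int(np.searchsorted(edges, inp.D, side="right"))
    on_edge = bool(np.any(np.abs(edges - inp.D) <= edge_tol))
    return N, on_edge


def plan_beta(diameters, w0: float = 30.0, NB: int = 4,
              beta_grid=None, exclude_edges: bool = False) -> list[float]:
    """All grid values of beta for which the predictor maps the given
    diameters to pairwise distinct branches.  With ``exclude_edges`` a
    beta is also rejected when any diameter sits exactly on a band edge
    (where the prediction is ambiguous).  Returns the qualifying beta
    values, possibly empty."""
    diameters = sorted(set(float(d) for d in diameters))
    if any(d >= 2 * w0 for d in diameters):
        raise ValueError("all diameters must be below 2 w0")
    if beta_grid is None:
        beta_grid = np.round(np.arange(0.1, 0.95, 0.1), 10)
    good = []
    for b in beta_grid:
        picks = [predict_branch(PredictionInput(D=d, beta=float(b), w0=w0,
                                                NB=NB)) for d in diameters]
        branches = [n for n, _ in picks]
        if len(set(branches)) < len(diameters):
            continue
        if exclude_edges and any(e for _, e in picks):
            continue
        good.append(float(b))
    return good


def branch_table(diameters, betas, w0: float = 30.0, NB: int = 4):
    """Predicted branch for every (D, beta) pair, as a list of dicts
    (CSV-friendly: D, beta, branch, on_edge)."""
    rows = []
    for d in diameters:
        for b in betas:
            n, edge = predict_branch(
                PredictionInput(D=float(d), beta=float(b), w0=w0, NB=NB))
            rows.append({"D": float(d), "beta": float(b),
                         "branch": n, "on_edge": edge})
    return rows
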