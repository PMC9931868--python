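"""Model selection criteria (AIC, SC, MSC) and best-model choice.

Least-squares forms without the additive Gaussian constants (they cancel in
comparisons):

    AIC = n ln(sswres/n) + 2p
    SC  = n ln(sswres/n) + p ln(n)          (Schwarz/Bayesian criterion)
    MSC = ln[ sum w (y - ybar)^2 / sum w (y - yhat)^2 ] - 2p/n

MSC is "higher is better"; AIC/SC are "lower is better".  A perfect fit
(sswres = 0) maps to the appropriate infinite sentinel so it orders ahead
of every finite value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def aic(n: int, p: int, sswres: float) -> float:
    """Akaike information criterion for a weighted least-squares fit."""
    if n <= p:
        raise ValueError("need n > p")
    if sswres < 0:
        raise ValueError("sswres must be non-negative")
    if sswres == 0:
        return -np.inf
    return n * np.log(sswres / n) + 2.0 * p


def sc(n: int, p: int, sswres: float) -> float:
    """Schwarz criterion (BIC form) for a weighted least-squares fit."""
    if n <= p:
        raise ValueError("need n > p")
    if sswres < 0:
        raise ValueError("sswres must be non-negative")
    if sswres == 0:
        return -np.inf
    return n * np.log(sswres / n) + p * np.log(n)


def msc(weights, observed, fitted, p: int) -> float:
    """Model selection criterion; higher is better."""
    w = np.asarray(weights, float)
    y = np.asarray(observed, float)
    yhat = np.asarray(fitted, float)
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot <= 0:
        raise ValueError("observed series has zero weighted variance")
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    n = y.size
    if ss_res == 0:
        return np.inf
    return np.log(ss_tot / ss_res) - 2.0 * p / n


@dataclass
class SelectionReport:
    """Criteria table and the winning model for one region's fits."""

    table: dict            # model -> {aic, sc, msc, sswres, p}
    winner: str
    rule: str

    def to_dict(self) -> dict:
        return {"table": self.table, "winner": self.winner, "rule": self.rule}


def select_model(fits) -> SelectionReport:
    """Pick the best model: lowest AIC; ties by lowest SC, then fewest parameters."""
    converged = [f for f in fits if f.converged]
    if len(converged) < 2:
        raise ValueError("need at least 2 converged fits to select a model")
    table = {f.model: {"aic": f.aic, "sc": f.sc, "msc": f.msc,
                       "sswres": f.sswres, "p": f.p} for f in converged}
    best = min(converged, key=lambda f: f.aic)
    tied = [f for f in converged if abs(f.aic - best.aic) < 1e-9
            or (np.isinf(f.aic) and np.isinf(best.aic))]
    rule = "lowest AIC"
    if len(tied) > 1:
        best_sc = min(f.sc for f in tied)
        tied_sc = [f for f in tied if abs(f.sc - best_sc) < 1e-9
                   or (np.isinf(f.sc) and np.isinf(best_sc))]
        rule = "AIC tie -> lowest SC"
        if len(tied_sc) > 1:
            tied_sc.sort(key=lambda f: f.p)
            rule = "AIC and SC tie -> fewest parameters"
        best = tied_sc[0]
    return SelectionReport(table=table, winner=best.model, rule=rule)
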