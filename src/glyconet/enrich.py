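"""Glycan-motif enrichment from predicted binding.

For every host, glycans are split into predicted binders (predicted
Z-score above 1.645, the one-sided 95% normal quantile used for glycan
array calls) and non-binders.  Each motif's 0/1 presence indicator is
compared between the two groups by a one-tailed Welch's t test
(binders greater), p values are corrected per host by Holm-Šidák, and
significant motifs are ranked by adjusted p; a motif's median rank
across the hosts where it is significant summarizes its overall
relevance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glycoparse import extract_motifs

BINDER_THRESHOLD = 1.645


@dataclass
class EnrichmentResult:
    motif: str
    host: str
    t: float
    df: float
    p: float
    p_adj: float
    significant: bool
    rank: float


def call_binders(z_hat, threshold: float = BINDER_THRESHOLD) -> np.ndarray:
    """Predicted-binder calls: strictly ``z_hat > threshold``."""
    return np.asarray(z_hat, dtype=np.float64) > threshold


def welch_t(x, y, alternative: str = "greater") -> tuple[float, float, float]:
    """Welch's unequal-variance t test from the closed-form formulas.

    Returns (t, Welch-Satterthwaite df, one- or two-tailed p).  Degenerate
    zero-variance samples get sentinels: equal means -> (0, nx+ny-2, 1);
    unequal means -> t = +/-inf with p = 0 or 1 by sign (for
    ``alternative="greater"``).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        t = np.inf if mx > my else -np.inf
        df = float(nx + ny - 2)
    else:
        se2 = vx / nx + vy / ny
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    elif alternative == "two-sided":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), float(df), p


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Šidák step-down adjusted p values, in the input order.

    Sort ascending; ``adj_(i) = 1 - (1 - p_(i))^(m-i+1)`` (1-based i),
    made monotone non-decreasing by a running maximum.
    """
    p = np.asarray(pvals, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def _presence_matrix(glycans: list[str], motifs: list[str]) -> np.ndarray:
    """0/1 matrix: glycan i contains motif j (any multiplicity)."""
    pres = np.zeros((len(glycans), len(motifs)), dtype=np.float64)
    index = {m: j for j, m in enumerate(motifs)}
    for i, g in enumerate(glycans):
        for m in extract_motifs(g, max_len=3):
            j = index.get(m)
            if j is not None:
                pres[i, j] = 1.0
    return pres


def enrich_motifs(predictions: dict[str, tuple[list[str], np.ndarray]],
                  motifs: list[str] | None = None, alpha: float = 0.05,
                  threshold: float = BINDER_THRESHOLD
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-host motif enrichment over predicted binding.

    ``predictions`` maps host -> (glycans, predicted z per glycan).  If
    `motifs` is None the union of all length<=3 motifs over each host's
    glycans is tested.  Hosts with fewer than 2 binders or 2 non-binders
    are skipped with a warning.

    Returns (per-host result table, per-motif summary with the median
    rank across hosts where the motif is significant).
    """
    rows: list[EnrichmentResult] = []
    for host, (glycans, z_hat) in predictions.items():
        z_hat = np.asarray(z_hat, dtype=np.float64)
        if len(glycans) != z_hat.size:
            raise ValueError(f"host {host!r}: glycans and predictions differ")
        host_motifs = motifs if motifs is not None else \
            sorted({m for g in glycans for m in extract_motifs(g, max_len=3)})
        if not host_motifs:
            raise ValueError("empty motif set")
        binders = call_binders(z_hat, threshold)
        if binders.sum() < 2 or (~binders).sum() < 2:
            warnings.warn(f"host {host!r}: need >= 2 binders and >= 2 "
                          "non-binders; skipped")
            continue
        pres = _presence_matrix(glycans, host_motifs)
        stats_rows = [welch_t(pres[binders, j], pres[~binders, j], "greater")
                      for j in range(len(host_motifs))]
        t = np.array([s[0] for s in stats_rows])
        df = np.array([s[1] for s in stats_rows])
        p = np.array([s[2] for s in stats_rows])
        p_adj = holm_sidak(p)
        sig = p_adj < alpha
        ranks = stats.rankdata(p_adj, method="average")
        for j, m in enumerate(host_motifs):
            rows.append(EnrichmentResult(
                motif=m, host=host, t=float(t[j]), df=float(df[j]),
                p=float(p[j]), p_adj=float(p_adj[j]),
                significant=bool(sig[j]), rank=float(ranks[j])))
    table = pd.DataFrame([vars(r) for r in rows])
    if table.empty:
        return table, pd.DataFrame(columns=["motif", "n_hosts_significant",
                                            "median_rank"])
    sig_tab = table[table["significant"]]
    summary = (sig_tab.groupby("motif")["rank"]
               .agg(n_hosts_significant="size", median_rank="median")
               .reset_index()
               .sort_values(["median_rank", "motif"])
               .reset_index(drop=True))
    return table, summary
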