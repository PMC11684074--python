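"""Adapted MaxLink candidate prioritization.

Guilt-by-association screening around a seed set of disease genes (here
tagged ``"EMT"``): the immediate network neighbours of the seeds become
candidates, then two sequential filters are applied —

1. *annotation filter*: candidates already carrying cancer-related Disease
   Ontology terms are removed (their disease link is not novel);
2. *connectivity filter*: a candidate's connectivity to seed genes is
   largely explained by its overall degree; a loess fit of seed-connectivity
   on total degree with a pointwise confidence band identifies candidates
   whose seed-connectivity is *consistent* with that degree-driven trend,
   and those are eliminated as pseudo-associations.  Survivors are the
   outliers — by default on either side of the band (``keep="both"``), or
   only above it (``keep="above"``).

Candidate state is tracked in a DataFrame (the candidate table) with a
forward-only ``status`` column: ``candidate → removed_annotation /
removed_connectivity / final``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .graph_core import tagged_nodes

logger = logging.getLogger(__name__)

SEED_TAG = "EMT"
#: the four cancer-related term keywords used by the annotation filter
DEFAULT_KEYWORDS = ("glioma", "cancer", "tumor", "cancer_DO_slim")

__all__ = [
    "SEED_TAG",
    "DEFAULT_KEYWORDS",
    "label_seeds",
    "find_candidates",
    "annotation_filter",
    "connectivity_filter",
    "loess_fit",
    "run_maxlink",
    "read_seed_list",
    "read_doid_map",
]


def read_seed_list(path: str | Path) -> list[str]:
    """Plain-text seed gene list, one symbol per line, blanks skipped."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_doid_map(path: str | Path) -> pd.DataFrame:
    """Gene→Disease-Ontology TSV with columns gene, doid, term_name, slim."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene", "doid", "term_name", "slim"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DOID map requires columns {sorted(required)}")
    return df


def label_seeds(net: nx.Graph, seed_genes: list[str]) -> nx.Graph:
    """Tag seed genes present in the network with ``"EMT"`` (on a copy).

    Symbol matching is exact and case-sensitive; off-network seeds are
    counted and logged.  An empty intersection is an error because every
    downstream stage keys off the tagged nodes.
    """
    net = net.copy()
    present = [g for g in seed_genes if g in net]
    missing = len(seed_genes) - len(present)
    if not present:
        raise ValueError("no seed gene matches a network node; cannot proceed")
    if missing:
        logger.info("%d seed symbol(s) not found in the network", missing)
    for g in present:
        tags = net.nodes[g].setdefault("tags", set())
        tags.add(SEED_TAG)
    return net


def find_candidates(net: nx.Graph) -> pd.DataFrame:
    """Immediate non-seed neighbours of the tagged seed genes.

    Returns the candidate table with per-candidate seed-connectivity
    (``emt_connectivity``), total degree and ``status="candidate"``.
    """
    seeds = tagged_nodes(net, SEED_TAG)
    if not seeds:
        raise ValueError("network has no nodes tagged as seeds; run label_seeds first")
    cands = sorted(set().union(*(net.neighbors(s) for s in seeds)) - seeds)
    rows = [
        {
            "symbol": c,
            "emt_connectivity": sum(1 for nb in net.neighbors(c) if nb in seeds),
            "total_degree": net.degree(c),
            "status": "candidate",
        }
        for c in cands
    ]
    df = pd.DataFrame(rows, columns=["symbol", "emt_connectivity", "total_degree", "status"])
    logger.info("%d candidate(s) from %d seed gene(s)", len(df), len(seeds))
    return df


def annotation_filter(
    cands: pd.DataFrame,
    doid_map: pd.DataFrame,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
) -> pd.DataFrame:
    """Remove candidates whose DO annotations contain cancer-related terms.

    A candidate is marked ``removed_annotation`` iff any of its DO term
    names or slim tags contains any keyword (case-insensitive substring
    match).  Candidates without a DO record are retained.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    kws = [k.lower() for k in keywords]
    by_gene = {
        g: list(zip(sub["doid"], sub["term_name"], sub["slim"]))
        for g, sub in doid_map.groupby("gene")
    }

    def hit(symbol: str) -> bool:
        for _, term, slim in by_gene.get(symbol, ()):
            text = f"{term} {slim}".lower()
            if any(k in text for k in kws):
                return True
        return False

    out = cands.copy()
    out["doids"] = out["symbol"].map(
        lambda s: [(d, t) for d, t, _ in by_gene.get(s, ())]
    )
    active = out["status"] == "candidate"
    removed = active & out["symbol"].map(hit)
    out.loc[removed, "status"] = "removed_annotation"
    logger.info(
        "annotation filter removed %d of %d candidate(s)", int(removed.sum()), int(active.sum())
    )
    return out


def _loess_pass(
    x: np.ndarray,
    y: np.ndarray,
    q: int,
    degree: int,
    delta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One loess pass with robustness weights ``delta``: (fitted, scale)."""
    n = x.size
    fitted = np.empty(n)
    scale = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(idx.size)
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 1e-9, None)  # keep the boundary point weakly in play
        w = w * np.clip(delta[idx], 1e-9, None)
        deg_eff = min(degree, len(np.unique(x[idx])) - 1)
        if deg_eff == 0:
            fitted[i] = float(np.average(y[idx], weights=w))
            resid = y[idx] - fitted[i]
        else:
            coeff = np.polyfit(x[idx], y[idx], deg_eff, w=np.sqrt(w))
            fitted[i] = float(np.polyval(coeff, x[i]))
            resid = y[idx] - np.polyval(coeff, x[idx])
        scale[i] = float(np.sqrt(np.average(resid**2, weights=w)))
    return fitted, scale


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    robust_iters: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust local polynomial (loess) fit evaluated at the data points.

    For each point, the ``ceil(span·n)`` nearest neighbours in ``x`` are
    tricube-weighted and a weighted polynomial of the requested degree
    (reduced when the window has too few distinct abscissae) is fitted.
    Following Cleveland's loess, ``robust_iters`` bisquare reweighting
    passes down-weight outlying points, so the trend and its residual
    scale describe the bulk of the data rather than the outliers the
    downstream filter is meant to expose.

    Returns ``(fitted, scale)`` where ``scale`` is the local weighted
    residual standard deviation — the half-width unit of the pointwise
    confidence band.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("loess needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x-range: all abscissae identical, loess undefined")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    q = max(degree + 2, int(np.ceil(span * n)))
    q = min(q, n)
    delta = np.ones(n)
    fitted, scale = _loess_pass(x, y, q, degree, delta)
    for _ in range(robust_iters):
        resid = y - fitted
        s = float(np.median(np.abs(resid)))
        if s == 0:
            break
        u = resid / (6.0 * s)
        delta = np.clip(1.0 - u**2, 0.0, None) ** 2
        fitted, scale = _loess_pass(x, y, q, degree, delta)
    return fitted, scale


def connectivity_filter(
    cands: pd.DataFrame,
    span: float = 0.75,
    ci_level: float = 0.95,
    degree: int = 2,
    keep: str = "both",
) -> pd.DataFrame:
    """Eliminate candidates whose seed-connectivity matches the degree trend.

    Loess of ``emt_connectivity`` on ``total_degree`` over the surviving
    candidates; the pointwise band is ``fit ± z(ci_level) · scale``.
    Candidates inside the band are marked ``removed_connectivity``;
    outliers become ``final``.  With ``keep="above"`` only above-band
    outliers survive (below-band ones are removed too).
    """
    if keep not in ("both", "above"):
        raise ValueError("keep must be 'both' or 'above'")
    out = cands.copy()
    active = out.index[out["status"] == "candidate"]
    if len(active) < 10:
        raise ValueError(
            f"connectivity filter needs >= 10 surviving candidates, got {len(active)}"
        )
    x = out.loc[active, "total_degree"].to_numpy(dtype=float)
    y = out.loc[active, "emt_connectivity"].to_numpy(dtype=float)
    fitted, scale = loess_fit(x, y, span=span, degree=degree)
    z = float(norm.ppf(0.5 + ci_level / 2.0))
    resid = y - fitted
    band = z * scale
    if keep == "both":
        survives = np.abs(resid) > band
    else:
        survives = resid > band
    out.loc[active, "loess_fit"] = fitted
    out.loc[active, "loess_band"] = band
    out.loc[active, "status"] = np.where(survives, "final", "removed_connectivity")
    logger.info(
        "connectivity filter removed %d of %d candidate(s); %d final",
        int((~survives).sum()),
        len(active),
        int(survives.sum()),
    )
    return out


def run_maxlink(
    net: nx.Graph,
    seed_genes: list[str],
    doid_map: pd.DataFrame,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    span: float = 0.75,
    ci_level: float = 0.95,
    keep: str = "both",
) -> pd.DataFrame:
    """Full pipeline: label seeds → candidates → annotation → connectivity."""
    labelled = label_seeds(net, seed_genes)
    cands = find_candidates(labelled)
    cands = annotation_filter(cands, doid_map, keywords=keywords)
    cands = connectivity_filter(cands, span=span, ci_level=ci_level, keep=keep)
    return cands
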