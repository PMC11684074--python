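"""Cohort assembly, fold change, Kruskal-Wallis testing and hit calling.

Patient tumour samples are split by their TNM staging code: ``N0`` with
``M0`` (any T) is *primary-site* disease, nodal spread ``N1/N2/N3`` (any M)
is *metastasized*, and any missing field (``TX``/``NX``/``MX``) excludes the
sample.  Normal-tissue samples are taken as flagged in the metadata
(``source = normal``) regardless of TNM.

Per gene, cancer type and transition (normal→primary, primary→metastatic)
the fold change of cohort mean FPKM is computed with a small pseudocount,
its significance assessed with a two-group Kruskal-Wallis test, and the
result stratified into the printed significance bands:

==============  ======================================
high            \\|log2FC| > 2 and P < 0.001
medium          1 < \\|log2FC| < 2 and 0.001 < P < 0.01
low             1 < \\|log2FC| < 2 and 0.01 < P < 0.05
non_significant P > 0.05
unclassified    anything matching no band above
==============  ======================================

The bands are applied with strict inequalities exactly as printed; gaps
(e.g. \\|log2FC| > 2 with 0.001 < P) fall into ``unclassified`` rather than
being silently widened.  A gene is a *hit* when its primary→metastatic tier
is high or medium.  No multiple-testing correction enters tier assignment
(a Benjamini-Hochberg column is emitted for information only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TRANSITIONS: dict[str, tuple[str, str]] = {
    "normal_primary": ("normal", "primary"),
    "primary_metastatic": ("primary", "metastatic"),
}
HIT_TRANSITION = "primary_metastatic"
HIT_TIERS = ("high", "medium")

__all__ = [
    "ExpressionStudy",
    "TRANSITIONS",
    "classify_tnm",
    "build_cohorts",
    "fold_change",
    "kruskal_wallis",
    "stratify",
    "call_hits",
    "read_expression",
    "read_metadata",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """FPKM matrix TSV: first column gene symbols, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, cancer_type, source, T, N, M."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "cancer_type", "source", "T", "N", "M"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata requires columns {sorted(required)}")
    return df.set_index("sample_id")


def _code_char(code: str, letter: str) -> str:
    """First character after the stage letter; validates the prefix."""
    code = str(code).strip().upper()
    if len(code) < 2 or code[0] != letter:
        raise ValueError(f"malformed {letter} code {code!r}")
    c = code[1]
    if c != "X" and not c.isdigit():
        raise ValueError(f"malformed {letter} code {code!r}")
    return c


def classify_tnm(t: str, n: str, m: str, mode: str = "strict") -> str:
    """Stage a tumour sample from its TNM codes.

    Returns ``"primary"``, ``"metastasized"`` or ``"excluded"``.  Any X
    field excludes the sample.  ``N0`` with ``M0`` is primary; ``N1/2/3``
    (any M) is metastasized.  The leftover combination ``N0`` with ``M1``
    is excluded with a warning under ``mode="strict"`` (the literal staging
    rule) and counted as metastasized under ``mode="inclusive"``.
    """
    if mode not in ("strict", "inclusive"):
        raise ValueError("mode must be 'strict' or 'inclusive'")
    tc = _code_char(t, "T")
    nc = _code_char(n, "N")
    mc = _code_char(m, "M")
    if "X" in (tc, nc, mc):
        return "excluded"
    if nc == "0" and mc == "0":
        return "primary"
    if nc in "123":
        return "metastasized"
    if mode == "inclusive" and mc != "0":
        return "metastasized"
    logger.warning("TNM combination (%s,%s,%s) matches no stage rule; excluded", t, n, m)
    return "excluded"


@dataclass
class ExpressionStudy:
    """FPKM matrix, sample metadata and the resolved per-cancer cohorts."""

    matrix: pd.DataFrame
    meta: pd.DataFrame
    cohorts: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def cohort(self, cancer_type: str, name: str) -> list[str]:
        return self.cohorts.get(cancer_type, {}).get(name, [])


def build_cohorts(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "strict",
) -> ExpressionStudy:
    """Resolve normal / primary / metastatic cohorts per cancer type.

    Every matrix column must have metadata.  Normals are the samples with
    ``source == normal``; tumour samples are staged with
    :func:`classify_tnm` (malformed codes raise, naming the sample).
    Cohort sizes are logged per cancer type.
    """
    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}...")
    cohorts: dict[str, dict[str, list[str]]] = {}
    for sample in matrix.columns:
        row = meta.loc[sample]
        ct = str(row["cancer_type"])
        groups = cohorts.setdefault(
            ct, {"normal": [], "primary": [], "metastatic": []}
        )
        source = str(row["source"]).lower()
        if source == "normal":
            groups["normal"].append(sample)
            continue
        try:
            stage = classify_tnm(row["T"], row["N"], row["M"], mode=mode)
        except ValueError as exc:
            raise ValueError(f"sample {sample}: {exc}") from exc
        if stage == "primary":
            groups["primary"].append(sample)
        elif stage == "metastasized":
            groups["metastatic"].append(sample)
    for ct, groups in cohorts.items():
        logger.info(
            "%s cohorts: normal=%d primary=%d metastatic=%d",
            ct,
            len(groups["normal"]),
            len(groups["primary"]),
            len(groups["metastatic"]),
        )
    return ExpressionStudy(matrix=matrix, meta=meta, cohorts=cohorts)


def fold_change(
    group_a: np.ndarray,
    group_b: np.ndarray,
    eps: float = 1e-3,
) -> tuple[float, float]:
    """(FC, log2FC) of mean expression across a transition (a → b).

    ``fc = (mean_b + eps) / (mean_a + eps)`` with a small FPKM pseudocount
    guarding zero means (its use on a zero mean is logged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ma, mb = float(a.mean()), float(b.mean())
    if ma == 0.0 or mb == 0.0:
        logger.info("zero cohort mean; pseudocount eps=%g applied", eps)
    fc = (mb + eps) / (ma + eps)
    return fc, float(np.log2(fc))


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H and p (tie-corrected, chi-square reference).

    By convention, fully tied data (all values identical) yield
    ``H = 0, p = 1`` instead of an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


def stratify(log2fc: float, p: float) -> str:
    """Significance tier from (log2FC, P) with strict printed bounds."""
    a = abs(log2fc)
    if a > 2 and p < 0.001:
        return "high"
    if 1 < a < 2 and 0.001 < p < 0.01:
        return "medium"
    if 1 < a < 2 and 0.01 < p < 0.05:
        return "low"
    if p > 0.05:
        return "non_significant"
    return "unclassified"


def call_hits(
    cands: pd.DataFrame,
    study: ExpressionStudy,
    transitions: tuple[str, ...] = ("normal_primary", "primary_metastatic"),
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Differential-expression hit table for the final candidates.

    Every final candidate is evaluated per cancer type and transition;
    a transition is skipped (with a warning) for a cancer type whose
    required cohort is empty.  ``is_hit`` is true when the
    primary→metastatic tier is high or medium; a gene appears once per
    cancer type in which it is a hit.  Candidates absent from the matrix
    are skipped and logged.  ``p_bh`` is an informational
    Benjamini-Hochberg adjustment within each (cancer type, transition)
    and never enters tier assignment.
    """
    final = cands.loc[cands["status"] == "final", "symbol"].tolist()
    missing = [g for g in final if g not in study.matrix.index]
    if missing:
        logger.info("%d final candidate(s) absent from the matrix; skipped", len(missing))
    genes = [g for g in final if g in study.matrix.index]
    rows = []
    for ct, groups in study.cohorts.items():
        for tname in transitions:
            ga, gb = TRANSITIONS[tname]
            a_ids = groups.get(ga, [])
            b_ids = groups.get(gb, [])
            if not a_ids or not b_ids:
                logger.warning("%s: transition %s skipped (empty cohort)", ct, tname)
                continue
            for gene in genes:
                a = study.matrix.loc[gene, a_ids].to_numpy(dtype=float)
                b = study.matrix.loc[gene, b_ids].to_numpy(dtype=float)
                fc, l2 = fold_change(a, b, eps=eps)
                _, p = kruskal_wallis(a, b)
                tier = stratify(l2, p)
                rows.append(
                    {
                        "gene": gene,
                        "cancer_type": ct,
                        "transition": tname,
                        "fc": fc,
                        "log2fc": l2,
                        "p_value": p,
                        "tier": tier,
                        "is_hit": tier in HIT_TIERS and tname == HIT_TRANSITION,
                    }
                )
    hits = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cancer_type",
            "transition",
            "fc",
            "log2fc",
            "p_value",
            "tier",
            "is_hit",
        ],
    )
    if len(hits):
        hits["p_bh"] = np.nan
        for _, idx in hits.groupby(["cancer_type", "transition"]).groups.items():
            hits.loc[idx, "p_bh"] = multipletests(
                hits.loc[idx, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    else:
        hits["p_bh"] = pd.Series(dtype=float)
    return hits
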