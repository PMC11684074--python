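"""Seeded synthetic inputs for the whole pipeline.

Everything the toolkit consumes — a heavy-tailed PPI network with an
expansion pool, a seed ("EMT") gene list, gene→Disease-Ontology
annotations, and log-normal FPKM cohorts with planted fold changes — is
generated here as a pure, deterministic function of a :class:`SynthConfig`.

The generator plants three kinds of ground truth so recovery can be
measured end-to-end:

* *planted hit genes* (default 10): low-degree nodes wired to extra
  randomly chosen seed genes so their seed-connectivity far exceeds the
  degree-driven trend — they are candidates that survive both MaxLink
  filters by construction — and whose metastatic-cohort expression carries
  a planted log2 fold change (default 3);
* a *planted specific neighbour*: one more such low-degree excess-
  connectivity node, without an expression effect;
* a *planted promiscuous hub*: a very high-degree non-seed node whose
  seed-connectivity is left at its natural, degree-explained level, so the
  connectivity filter should eliminate it.

None of the planted nodes receives a cancer Disease-Ontology term, so all
of them pass the annotation filter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthBundle", "synth_network", "synth_annotations",
           "synth_expression", "generate_all", "write_fixture_dir"]

_CANCER_TERMS = [
    ("DOID:0060058", "malignant glioma", "cancer_DO_slim"),
    ("DOID:1612", "breast cancer", "cancer_DO_slim"),
    ("DOID:3571", "liver tumor", ""),
    ("DOID:1324", "lung cancer", "cancer_DO_slim"),
]
_BENIGN_TERMS = [
    ("DOID:9352", "diabetes mellitus", ""),
    ("DOID:2841", "asthma", ""),
    ("DOID:10763", "hypertension", ""),
    ("DOID:7148", "rheumatoid arthritis", ""),
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic inputs (all seeded).

    The expression block emulates FPKM cohorts: per-gene baselines are
    log-normal with log-mean ``fpkm_logmean`` (≈7 FPKM) and within-cohort
    log-SD ``fpkm_logsd`` (typical spread of log-FPKM across patients).
    """

    n_nodes: int = 200
    n_edges_per_node: int = 4
    seed: int = 0
    seed_gene_fraction: float = 0.175
    cancer_doid_fraction: float = 0.3
    n_planted_hits: int = 10
    planted_log2fc: float = 3.0
    planted_transition: str = "primary_metastatic"
    planted_seed_links: int = 8
    planted: tuple[tuple[str, str, float], ...] | None = None
    cohort_sizes: dict = field(
        default_factory=lambda: {"normal": 30, "primary": 30, "metastatic": 30}
    )
    fpkm_logmean: float = 2.0
    fpkm_logsd: float = 0.5
    n_pool_nodes: int = 40
    tnm_missing_fraction: float = 0.05
    cancer_type: str = "SYN"

    def __post_init__(self):
        for name in ("seed_gene_fraction", "cancer_doid_fraction", "tnm_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(v < 2 for v in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be >= 2")


@dataclass
class SynthBundle:
    """Everything one seeded generation run produces."""

    config: SynthConfig
    net: nx.Graph
    pool: pd.DataFrame
    seeds: list[str]
    doid_map: pd.DataFrame
    planted_hits: list[str]
    planted_specific: str
    planted_hub: str
    matrix: pd.DataFrame
    meta: pd.DataFrame


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def synth_network(cfg: SynthConfig) -> tuple[nx.Graph, pd.DataFrame]:
    """Preferential-attachment network plus a disjoint expansion pool.

    The graph starts from a complete seed graph on ``m`` nodes and attaches
    each new node with ``m`` edges, so the edge count is exactly
    ``m(m−1)/2 + (n−m)·m``.  Edge confidences are uniform on [0.5, 1].
    Pool nodes (named ``P###``) attach 1-5 candidate edges each to
    degree-weighted network nodes, plus occasional pool-pool edges.
    """
    if cfg.n_nodes < 20:
        raise ValueError("n_nodes must be >= 20")
    m = cfg.n_edges_per_node
    rng = _rng(cfg, 1)
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(
        cfg.n_nodes, m, seed=ba_seed, initial_graph=nx.complete_graph(m)
    )
    mapping = {i: f"G{i:04d}" for i in g.nodes}
    net = nx.relabel_nodes(g, mapping)
    for a, b in sorted(net.edges):
        net.edges[a, b]["confidence"] = float(rng.uniform(0.5, 1.0))

    nodes = sorted(net.nodes)
    degrees = np.array([net.degree(n) for n in nodes], dtype=float)
    p_attach = degrees / degrees.sum()
    rows = []
    pool_names = [f"P{j:03d}" for j in range(cfg.n_pool_nodes)]
    for j, pname in enumerate(pool_names):
        n_links = int(rng.integers(1, 6))
        targets = rng.choice(len(nodes), size=min(n_links, len(nodes)), replace=False, p=p_attach)
        for t in targets:
            rows.append((pname, nodes[t], float(rng.uniform(0.5, 1.0))))
        if j > 0 and rng.uniform() < 0.3:
            other = pool_names[int(rng.integers(0, j))]
            rows.append((pname, other, float(rng.uniform(0.5, 1.0))))
    pool = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    return net, pool


def synth_annotations(
    net: nx.Graph, cfg: SynthConfig
) -> tuple[list[str], pd.DataFrame, list[str], str, str]:
    """Seed gene list, DOID map and planted ground truth.

    Returns ``(seeds, doid_map, planted_hits, planted_specific,
    planted_hub)``.  Planting wires each planted gene to
    ``cfg.planted_seed_links`` additional randomly chosen seed genes —
    these edges are added to ``net`` in place (confidences uniform on
    [0.5, 1]) — which is what makes planted genes connectivity-filter
    outliers by construction.
    """
    rng = _rng(cfg, 2)
    nodes = sorted(net.nodes)
    n = len(nodes)
    n_seeds = int(round(cfg.seed_gene_fraction * n))

    by_degree = sorted(nodes, key=lambda x: (-net.degree(x), x))
    low_degree = [x for x in nodes if net.degree(x) <= cfg.n_edges_per_node + 2]
    n_plant = cfg.n_planted_hits + 1  # +1 for the specific neighbour
    if len(low_degree) < n_plant:
        raise ValueError("not enough low-degree nodes to plant into")
    planted_nodes = [low_degree[i] for i in rng.choice(len(low_degree), n_plant, replace=False)]
    planted_hits = sorted(planted_nodes[: cfg.n_planted_hits])
    planted_specific = planted_nodes[-1]

    # hub: the best-connected node that is neither planted nor (later) a seed
    hub_pool = [x for x in by_degree if x not in planted_nodes]
    planted_hub = hub_pool[0]

    never_seed = set(planted_nodes) | {planted_hub}
    eligible = [x for x in nodes if x not in never_seed]
    if n_seeds == 0:
        seeds: list[str] = []
    else:
        n_seeds = min(n_seeds, len(eligible))
        seeds = sorted(eligible[i] for i in rng.choice(len(eligible), n_seeds, replace=False))

    # plant excess seed-connectivity: extra edges to randomly chosen seeds.
    # Link counts are spread over [planted_seed_links/2, 3/2·planted_seed_links]
    # so the planted genes scatter across the degree axis instead of forming
    # a cluster that the connectivity trend would absorb as its own signal.
    seed_arr = list(seeds)
    spread = np.linspace(
        max(3, cfg.planted_seed_links // 2),
        max(4, cfg.planted_seed_links + cfg.planted_seed_links // 2),
        num=len(planted_nodes),
    ).round().astype(int)
    for pnode, n_links in zip(planted_nodes, spread):
        if not seed_arr:
            break
        current = set(net.neighbors(pnode))
        free = [s for s in seed_arr if s not in current and s != pnode]
        k = min(int(n_links), len(free))
        for i in rng.choice(len(free), k, replace=False):
            net.add_edge(pnode, free[i], confidence=float(rng.uniform(0.5, 1.0)))

    # DOID map over candidates (neighbours of seeds that are not seeds)
    seed_set = set(seeds)
    cands = sorted(
        set().union(*(set(net.neighbors(s)) for s in seed_set)) - seed_set
    ) if seed_set else []
    rows = []
    protected = set(planted_nodes) | {planted_hub}
    for c in cands:
        if c in protected:
            terms = [_BENIGN_TERMS[int(rng.integers(len(_BENIGN_TERMS)))]]
        elif rng.uniform() < cfg.cancer_doid_fraction:
            terms = [_CANCER_TERMS[int(rng.integers(len(_CANCER_TERMS)))]]
        elif rng.uniform() < 0.3:
            terms = [_BENIGN_TERMS[int(rng.integers(len(_BENIGN_TERMS)))]]
        else:
            terms = []
        for doid, name, slim in terms:
            rows.append((c, doid, name, slim))
    doid_map = pd.DataFrame(rows, columns=["gene", "doid", "term_name", "slim"])
    logger.info(
        "synth annotations: %d seeds, %d candidates, %d DOID rows",
        len(seeds), len(cands), len(doid_map),
    )
    return seeds, doid_map, planted_hits, planted_specific, planted_hub


def synth_expression(
    genes: list[str], cfg: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal FPKM cohorts with planted fold changes.

    Returns ``(matrix, meta)``.  Baseline per-gene log-means are normal
    around ``fpkm_logmean``; per-sample values are log-normal with SD
    ``fpkm_logsd``.  Planted ``(gene, transition, log2fc)`` effects shift
    the later cohort's log-mean by ``log2fc·ln 2``.  TNM codes are
    generated consistent with cohort membership; an extra
    ``tnm_missing_fraction`` of tumour samples carries an X field so the
    exclusion rule is exercised without shrinking the cohorts.
    """
    rng = _rng(cfg, 3)
    genes = list(genes)
    planted = cfg.planted or ()
    planted_by_gene: dict[str, list[tuple[str, float]]] = {}
    for g, trans, l2 in planted:
        if g not in genes:
            raise ValueError(f"planted gene {g} not in gene universe")
        planted_by_gene.setdefault(g, []).append((trans, l2))

    mu = rng.normal(cfg.fpkm_logmean, 0.5, size=len(genes))
    cohort_names = ("normal", "primary", "metastatic")
    samples: list[str] = []
    meta_rows = []
    values = {}

    def tnm_for(cohort: str, excluded: bool) -> tuple[str, str, str]:
        t = f"T{int(rng.integers(1, 5))}"
        if cohort == "normal":
            t, n_code, m_code = "", "", ""
        elif cohort == "primary":
            n_code, m_code = "N0", "M0"
        else:
            n_code = f"N{int(rng.integers(1, 4))}"
            m_code = f"M{int(rng.integers(0, 2))}"
        if excluded:
            which = int(rng.integers(3))
            t, n_code, m_code = [
                (x if i != which else x[:1] + "X") if x else x
                for i, x in enumerate((t or "T1", n_code or "N0", m_code or "M0"))
            ]
        return t, n_code, m_code

    prefix = {"normal": "NOR", "primary": "PRI", "metastatic": "MET"}
    for cohort in cohort_names:
        size = cfg.cohort_sizes[cohort]
        n_extra = (
            int(np.ceil(cfg.tnm_missing_fraction * size)) if cohort != "normal" else 0
        )
        for i in range(size + n_extra):
            excluded = i >= size
            sid = f"{prefix[cohort]}{i:03d}"
            samples.append(sid)
            t, n_code, m_code = tnm_for(cohort, excluded)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cancer_type": cfg.cancer_type,
                    "source": "normal" if cohort == "normal" and not excluded else "tumour",
                    "T": t,
                    "N": n_code,
                    "M": m_code,
                }
            )
            # a planted effect switches on at the transition's later stage and
            # persists through all subsequent stages
            stage_order = {"normal": 0, "primary": 1, "metastatic": 2}
            shift = np.zeros(len(genes))
            for gi, g in enumerate(genes):
                for trans, l2 in planted_by_gene.get(g, ()):
                    later = trans.split("_")[-1]
                    if stage_order[cohort] >= stage_order[later]:
                        shift[gi] += l2 * np.log(2)
            values[sid] = np.exp(rng.normal(mu + shift, cfg.fpkm_logsd))
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return matrix, meta


def generate_all(cfg: SynthConfig) -> SynthBundle:
    """Run all three generators coherently for one configuration."""
    net, pool = synth_network(cfg)
    seeds, doid_map, hits, specific, hub = synth_annotations(net, cfg)
    if cfg.planted is None:
        planted = tuple(
            (g, cfg.planted_transition, cfg.planted_log2fc) for g in hits
        )
        cfg = dataclasses.replace(cfg, planted=planted)
    matrix, meta = synth_expression(sorted(net.nodes), cfg)
    return SynthBundle(
        config=cfg,
        net=net,
        pool=pool,
        seeds=seeds,
        doid_map=doid_map,
        planted_hits=hits,
        planted_specific=specific,
        planted_hub=hub,
        matrix=matrix,
        meta=meta,
    )


def write_fixture_dir(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write net.tsv, pool.tsv, seeds.txt, doid.tsv, fpkm.tsv, meta.tsv."""
    from .graph_core import write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.tsv" for k in ("net", "pool", "doid", "fpkm", "meta")}
    paths["seeds"] = outdir / "seeds.txt"
    write_network(bundle.net, paths["net"])
    bundle.pool.to_csv(paths["pool"], sep="\t", index=False, float_format="%.6g")
    paths["seeds"].write_text("\n".join(bundle.seeds) + "\n")
    bundle.doid_map.to_csv(paths["doid"], sep="\t", index=False)
    bundle.matrix.to_csv(paths["fpkm"], sep="\t", float_format="%.6g")
    bundle.meta.to_csv(paths["meta"], sep="\t")
    return paths
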