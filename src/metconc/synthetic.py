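"""Synthetic benchmark generator with a known sparse generative link.

No public deposition exists for a complete concentration-modelling input
bundle (concentrations, molecular-descriptor matrix, reactant pairs,
pathway memberships), so this module generates all four with a known
ground truth, in exactly the file formats the rest of the package
consumes. The generative model mirrors the statistical structure the
concentration model assumes:

``-logC = b0 + sum_j c_j d_j + t * clustering_coefficient
          + offset * #(deviant pathway memberships) + N(0, sd)``

where only a small set of molecular descriptors carries nonzero
coefficients ``c_j`` (the recovery target for variable selection), the
clustering coefficient enters with a negative coefficient (denser
network neighbourhoods, higher concentrations), and each membership of a
designated "deviant" pathway adds a concentration-raising offset, the
way non-core pathways do for the MPF descriptor. The signal is exactly
linear in the assembled feature columns, so in the noiseless limit the
full pipeline can in principle recover it perfectly.

Descriptor columns are correlated Gaussians (Cholesky factor of a random
SPD correlation matrix) so that collinearity stresses selection
realistically. Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import Dataset, MetaboliteRecord, write_metabolite_table
from .features import FeatureMatrix
from .network import MetabolicNetwork, ReactantPair, reconstruct_network

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "write_inputs", "table4_fixture", "table4_dataset"]

ORGANISMS = ("eco", "sce")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark draw.

    Defaults emulate the reference study's scale: 130 metabolite records
    across two organisms, a sparse signal of 5 informative molecular
    descriptors out of 50, observation noise 0.2 on the -logC scale, a
    negative clustering-coefficient effect and a concentration-raising
    offset for a deviant pathway group.
    """

    n_metabolites: int = 130
    n_molecular_descriptors: int = 50
    n_pathways: int = 20
    n_informative: int = 5
    coefficients: tuple[float, ...] = (1.0, -0.8, 0.7, -0.6, 0.5)
    intercept: float = 3.5
    noise_sd: float = 0.2
    network_model: str = "erdos_renyi"  # or "barabasi_albert"
    mean_degree: float = 4.0
    topology_effect: float = -0.5
    deviant_pathway_offset: float = -1.0
    n_deviant_pathways: int = 3
    shared_fraction: float = 0.15  # metabolites measured in both organisms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.coefficients) != self.n_informative:
            raise ValueError("coefficients must have length n_informative")
        if self.n_informative > self.n_molecular_descriptors:
            raise ValueError("more informative descriptors than descriptors")
        if self.network_model not in ("erdos_renyi", "barabasi_albert"):
            raise ValueError(f"unknown network_model {self.network_model!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated benchmark."""

    informative: list[str]
    coefficients: dict[str, float]
    intercept: float
    topology_effect: float
    deviant_pathway_offset: float
    deviant_pathways: list[str]
    noise_sd: float
    descriptor_signal_variance: float  # analytic: c' Sigma c
    pathway_signal_variance: float  # analytic: offset^2 q (1-q)
    analytic_r2: float | None  # exact only when topology_effect == 0
    linear_predictor: pd.Series = field(repr=False, default=None)


def _correlated_gaussians(rng, n: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    W = rng.normal(size=(p, p)) / np.sqrt(p)
    sigma = W @ W.T + 0.5 * np.eye(p)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    L = np.linalg.cholesky(corr)
    Z = rng.normal(size=(n, p))
    return Z @ L.T, corr


def generate(
    cfg: SyntheticConfig,
) -> tuple[Dataset, FeatureMatrix, dict[str, MetabolicNetwork], dict[str, set[str]], SyntheticTruth]:
    """Draw one complete benchmark.

    Returns the dataset, the molecular-descriptor matrix (indexed by
    metabolite_id), one reconstructed network per organism, the
    pathway-membership map and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    # n_metabolites counts records (metabolite x organism measurements);
    # compounds shared between the organisms contribute two records each
    n_shared = int(round(cfg.shared_fraction * cfg.n_metabolites / 2))
    n_compounds = cfg.n_metabolites - n_shared
    mids = [f"m{i:04d}" for i in range(n_compounds)]
    desc_names = [f"desc_{j:03d}" for j in range(cfg.n_molecular_descriptors)]
    pathways = [f"Map{j:05d}" for j in range(1, cfg.n_pathways + 1)]
    deviant = pathways[: cfg.n_deviant_pathways]

    # molecular descriptors: shared per metabolite, correlated columns
    D, corr = _correlated_gaussians(rng, n_compounds, cfg.n_molecular_descriptors)
    molecular = FeatureMatrix(
        pd.DataFrame(D, index=mids, columns=desc_names),
        {c: "molecular" for c in desc_names},
    )
    inf_idx = sorted(rng.choice(cfg.n_molecular_descriptors, cfg.n_informative, replace=False))
    # the strongest informative descriptor plays the polarity role: -logC
    # rises with it, the way it does with the octanol/water partition coefficient
    desc_names[inf_idx[0]] = "ClogP"
    molecular.frame.columns = desc_names
    molecular.origin.index = desc_names
    informative = [desc_names[j] for j in inf_idx]
    coef = np.zeros(cfg.n_molecular_descriptors)
    for j, c in zip(inf_idx, cfg.coefficients):
        coef[j] = c

    # pathway memberships: per-pathway Bernoulli rates
    rates = rng.uniform(0.05, 0.3, size=cfg.n_pathways)
    members: dict[str, set[str]] = {m: set() for m in mids}
    for j, pw in enumerate(pathways):
        hits = rng.random(n_compounds) < rates[j]
        for i in np.flatnonzero(hits):
            members[mids[i]].add(pw)

    # organism assignment: a shared slice measured in both organisms
    shared = set(rng.choice(mids, n_shared, replace=False)) if n_shared else set()
    rest = [m for m in mids if m not in shared]
    org_of = {m: ORGANISMS[0] if rng.random() < 0.7 else ORGANISMS[1] for m in rest}

    record_keys: list[tuple[str, str]] = [(m, org_of[m]) for m in rest]
    record_keys += [(m, org) for m in sorted(shared) for org in ORGANISMS]
    record_keys.sort(key=lambda t: (t[0], t[1]))

    # per-organism networks from per-organism metabolite sets
    nets: dict[str, MetabolicNetwork] = {}
    pairs: list[ReactantPair] = []
    org_pathways = {
        ORGANISMS[0]: set(pathways[: int(0.8 * cfg.n_pathways)]),
        ORGANISMS[1]: set(pathways[int(0.2 * cfg.n_pathways) :]),
    }
    for org in ORGANISMS:
        nodes = sorted({m for m, o in record_keys if o == org})
        n = len(nodes)
        g_seed = int(rng.integers(2**31))
        if cfg.network_model == "erdos_renyi":
            g = nx.gnp_random_graph(n, min(1.0, cfg.mean_degree / max(n - 1, 1)), seed=g_seed)
        else:
            g = nx.barabasi_albert_graph(n, max(1, int(cfg.mean_degree // 2)), seed=g_seed)
        g = nx.relabel_nodes(g, dict(enumerate(nodes)))
        org_pool = sorted(org_pathways[org])
        for u, v in g.edges():
            tag = org_pool[int(rng.integers(len(org_pool)))]
            pairs.append(ReactantPair(u, v, frozenset({tag})))
        # decoys exercising both screening criteria
        for _ in range(max(2, n // 20)):
            u, v = (nodes[int(i)] for i in rng.integers(n, size=2))
            if u != v:
                pairs.append(ReactantPair(u, v, frozenset({"Map99999"})))
                pairs.append(ReactantPair(u, v, frozenset({org_pool[0]}), has_unspecified_residue=True))
        nets[org] = reconstruct_network(
            [p for p in pairs if p.substrate_id in set(nodes) and p.product_id in set(nodes)],
            org_pathways[org],
        )
        for node in nodes:  # isolated metabolites stay in the organism network
            nets[org].graph.add_node(node)

    # response
    records = []
    predictor = {}
    mid_pos = {m: i for i, m in enumerate(mids)}
    for m, org in record_keys:
        cc = nets[org].clustering_coefficient(m) if m in nets[org] else 0.0
        n_deviant_memberships = len(members[m] & set(deviant))
        lin = (
            cfg.intercept
            + float(D[mid_pos[m]] @ coef)
            + cfg.topology_effect * cc
            + cfg.deviant_pathway_offset * n_deviant_memberships
        )
        yv = lin + rng.normal(0.0, cfg.noise_sd)
        predictor[f"{m}:{org}"] = lin
        records.append(
            MetaboliteRecord(
                metabolite_id=m,
                name=m,
                organism=org,
                concentration=float(10.0 ** (-yv)),
                neg_log_c=None,
            )
        )
    dataset = Dataset(records, provenance={"generator": "metconc.synthetic", "seed": cfg.seed})

    desc_var = float(coef @ corr @ coef)
    # independent Bernoulli memberships: var(offset * sum_j B_j) = offset^2 * sum_j q_j(1-q_j)
    pw_var = float(
        cfg.deviant_pathway_offset**2
        * sum(rates[j] * (1.0 - rates[j]) for j in range(cfg.n_deviant_pathways))
    )
    if cfg.topology_effect == 0.0:
        total = desc_var + pw_var
        analytic_r2 = total / (total + cfg.noise_sd**2) if total + cfg.noise_sd**2 > 0 else None
    else:
        analytic_r2 = None
    truth = SyntheticTruth(
        informative=informative,
        coefficients={desc_names[j]: float(coef[j]) for j in inf_idx},
        intercept=cfg.intercept,
        topology_effect=cfg.topology_effect,
        deviant_pathway_offset=cfg.deviant_pathway_offset,
        deviant_pathways=list(deviant),
        noise_sd=cfg.noise_sd,
        descriptor_signal_variance=desc_var,
        pathway_signal_variance=pw_var,
        analytic_r2=analytic_r2,
        linear_predictor=pd.Series(predictor),
    )
    truth.reactant_pairs = pairs  # serialized by write_inputs
    truth.organism_pathways = org_pathways
    truth.pathways = pathways
    return dataset, molecular, nets, members, truth


def write_inputs(
    outdir: str | Path,
    dataset: Dataset,
    molecular: FeatureMatrix,
    members: dict[str, set[str]],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Serialize a generated benchmark in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": outdir / "metabolites.tsv",
        "molecular": outdir / "molecular_descriptors.csv",
        "reactant_pairs": outdir / "reactant_pairs.tsv",
        "pathway_membership": outdir / "pathway_membership.tsv",
        "organism_pathways": outdir / "organism_pathways.tsv",
    }
    write_metabolite_table(dataset, paths["metabolites"])
    molecular.to_csv(paths["molecular"])
    rows = [
        {
            "substrate_id": p.substrate_id,
            "product_id": p.product_id,
            "pathway_ids": ";".join(sorted(p.pathway_ids)),
            "unspecified_residue": int(p.has_unspecified_residue),
        }
        for p in truth.reactant_pairs
    ]
    pd.DataFrame(rows).to_csv(paths["reactant_pairs"], sep="\t", index=False)
    mem_rows = [
        {"metabolite_id": m, "pathway_id": pw} for m in sorted(members) for pw in sorted(members[m])
    ]
    pd.DataFrame(mem_rows).to_csv(paths["pathway_membership"], sep="\t", index=False)
    org_rows = [
        {"organism": org, "pathway_id": pw}
        for org in sorted(truth.organism_pathways)
        for pw in sorted(truth.organism_pathways[org])
    ]
    pd.DataFrame(org_rows).to_csv(paths["organism_pathways"], sep="\t", index=False)
    return paths


def table4_fixture() -> pd.DataFrame:
    """The packaged 14-metabolite deviant-pathway table.

    Columns: metabolite_id, name, -logCe in E. coli and S. cerevisiae
    (NA where no measurement is available) and CLogP.
    """
    ref = importlib.resources.files("metconc").joinpath("data/table4_mpf_metabolites.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def table4_dataset() -> tuple[Dataset, dict[str, float], list[str]]:
    """Fixture reshaped for :func:`metconc.features.pathway_deviation_table`.

    Returns a tidy Dataset (one record per metabolite x organism with a
    measured -logC), the CLogP map and the member-id list.
    """
    table = table4_fixture()
    records = []
    clogp = {}
    for row in table.itertuples(index=False):
        clogp[row.metabolite_id] = float(row.clogp)
        for org, col in (("eco", row.neg_log_c_eco), ("sce", row.neg_log_c_sce)):
            if not pd.isna(col):
                records.append(
                    MetaboliteRecord(
                        metabolite_id=row.metabolite_id,
                        name=str(row.name),
                        organism=org,
                        neg_log_c=float(col),
                    )
                )
    return Dataset(records, {"source": "packaged fixture"}), clogp, list(table["metabolite_id"])
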