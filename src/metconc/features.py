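"""Feature-matrix assembly, variance filtering, pathway variables and MPF.

The full descriptor table for concentration modelling concatenates three
families per metabolite x organism row:

* molecular descriptors (precomputed externally, e.g. DRAGON/MOE tables,
  consumed as delimited text and shared between organisms),
* network-topology descriptors (degree, clustering coefficient;
  organism-specific),
* binary pathway-membership variables, one per pathway (1 iff the
  metabolite participates in that pathway).

The MPF (Metabolite Pathways' Feature) descriptor collapses a set of
retained pathway variables into a single binary column: 1 iff the
metabolite participates in at least one of them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import Dataset, row_key

logger = logging.getLogger(__name__)

ORIGIN_TAGS = ("molecular", "topology", "pathway", "mpf")

__all__ = [
    "FeatureMatrix",
    "FilterReport",
    "pathway_variables",
    "preprocess",
    "filter_near_constant_pathways",
    "build_mpf",
    "clogp_bin_report",
    "pathway_deviation_table",
    "assemble",
    "read_pathway_membership",
]


class FeatureMatrix:
    """Named real matrix (rows: metabolite x organism) with column provenance.

    ``origin`` tags every column with its descriptor family
    (molecular / topology / pathway / mpf); tags survive subsetting,
    joining and filtering.
    """

    def __init__(self, frame: pd.DataFrame, origin: Mapping[str, str]):
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")
        missing = set(frame.columns) - set(origin)
        if missing:
            raise ValueError(f"columns without an origin tag: {sorted(missing)}")
        bad = {t for c, t in origin.items() if c in frame.columns and t not in ORIGIN_TAGS}
        if bad:
            raise ValueError(f"unknown origin tags {sorted(bad)}; expected {ORIGIN_TAGS}")
        self.frame = frame.astype(float)
        self.origin = pd.Series({c: origin[c] for c in frame.columns}, dtype=object)

    # -- basic protocol ----------------------------------------------------
    @property
    def row_keys(self) -> list[str]:
        return list(self.frame.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown columns: {missing}")
        return FeatureMatrix(self.frame[list(names)], self.origin.to_dict())

    def join(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not self.frame.index.equals(other.frame.index):
            raise ValueError("row keys differ; cannot join feature blocks")
        frame = pd.concat([self.frame, other.frame], axis=1)
        origin = {**self.origin.to_dict(), **other.origin.to_dict()}
        return FeatureMatrix(frame, origin)

    # -- io ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index_label="row_key")
        sidecar = path.with_suffix(path.suffix + ".origin.json")
        with open(sidecar, "w") as fh:
            json.dump(self.origin.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_csv(
        cls, path: str | Path, origin: Mapping[str, str] | None = None, strict: bool = True
    ) -> "FeatureMatrix":
        """Load a matrix written by :meth:`to_csv` (or any CSV with a header).

        ``strict`` rejects missing cells; in lenient mode they are
        mean-imputed per column with a logged count.
        """
        path = Path(path)
        frame = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=True)
        if origin is None:
            sidecar = path.with_suffix(path.suffix + ".origin.json")
            if sidecar.exists():
                with open(sidecar) as fh:
                    origin = json.load(fh)
            else:
                origin = {c: "molecular" for c in frame.columns}
        n_missing = int(frame.isna().to_numpy().sum())
        if n_missing:
            if strict:
                raise ValueError(
                    f"{path}: {n_missing} missing descriptor cell(s); "
                    "load with strict=False to mean-impute"
                )
            logger.warning("%s: mean-imputing %d missing cell(s)", path, n_missing)
            frame = frame.fillna(frame.mean())
        return cls(frame, origin)


@dataclass
class FilterReport:
    """Outcome of the variance-based descriptor filters."""

    removed_constant: list[str] = field(default_factory=list)
    removed_low_sd: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    sd_threshold: float = 0.001

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")


def preprocess(matrix: FeatureMatrix, sd_threshold: float = 0.001) -> tuple[FeatureMatrix, FilterReport]:
    """Drop all-constant columns and columns with sample sd below threshold.

    A constant descriptor carries no information for the dataset at hand;
    near-constant descriptors (sample standard deviation, n-1 denominator,
    below ``sd_threshold``) have too little statistical meaning. The
    operation is idempotent.
    """
    frame = matrix.frame
    constant = [c for c in frame.columns if frame[c].nunique(dropna=False) <= 1]
    rest = [c for c in frame.columns if c not in constant]
    sds = frame[rest].std(ddof=1)
    low_sd = [c for c in rest if sds[c] < sd_threshold]
    kept = [c for c in frame.columns if c not in constant and c not in low_sd]
    if not kept:
        raise ValueError("all descriptor columns removed by preprocessing")
    report = FilterReport(
        removed_constant=constant, removed_low_sd=low_sd, kept=kept, sd_threshold=sd_threshold
    )
    return matrix.subset(kept), report


def read_pathway_membership(path: str | Path) -> dict[str, set[str]]:
    """Read metabolite -> pathway memberships from TSV or GMT.

    TSV: two columns ``metabolite_id, pathway_id`` (one membership per
    row). GMT: ``pathway<TAB>description<TAB>member1<TAB>member2...``.
    """
    path = Path(path)
    members: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                pathway = parts[0]
                for mid in parts[2:]:
                    if mid:
                        members.setdefault(mid, set()).add(pathway)
        return members
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for row in frame.itertuples(index=False):
        members.setdefault(str(row.metabolite_id), set()).add(str(row.pathway_id))
    return members


def _resolve_metabolite(key: str) -> str:
    # row keys are "metabolite_id:organism"; bare metabolite ids pass through
    return key.split(":", 1)[0]


def pathway_variables(
    members: Mapping[str, set[str]], pathways: set[str], rows: Sequence[str]
) -> FeatureMatrix:
    """One binary column per pathway: 1 iff the row's metabolite is a member."""
    if not pathways:
        raise ValueError("pathway set must be non-empty")
    cols = sorted(pathways)
    data = np.zeros((len(rows), len(cols)))
    for i, key in enumerate(rows):
        mid = _resolve_metabolite(key)
        mem = members.get(mid, set())
        for j, pw in enumerate(cols):
            if pw in mem:
                data[i, j] = 1.0
    frame = pd.DataFrame(data, index=list(rows), columns=cols)
    return FeatureMatrix(frame, {c: "pathway" for c in cols})


def filter_near_constant_pathways(
    pv: FeatureMatrix, min_minority: int = 2
) -> tuple[FeatureMatrix, list[str]]:
    """Drop pathway variables with the same value for almost all metabolites.

    "Almost all" is quantified as a minority class smaller than
    ``min_minority`` rows (default 2).
    """
    keep, dropped = [], []
    for c in pv.column_names:
        counts = pv.frame[c].value_counts()
        minority = int(counts.min()) if len(counts) > 1 else 0
        (keep if minority >= min_minority else dropped).append(c)
    if not keep:
        raise ValueError("no pathway variable survived the near-constant filter")
    return pv.subset(keep), dropped


def build_mpf(
    members: Mapping[str, set[str]], selected_pathways: set[str], rows: Sequence[str]
) -> pd.Series:
    """MPF descriptor: 1 iff the metabolite is in any selected pathway.

    Equals the element-wise OR of the selected pathway-membership
    columns.
    """
    if not selected_pathways:
        raise ValueError("selected_pathways must be non-empty")
    values = [
        1.0 if (members.get(_resolve_metabolite(k), set()) & selected_pathways) else 0.0
        for k in rows
    ]
    return pd.Series(values, index=list(rows), name="MPF")


def clogp_bin_report(
    dataset: Dataset, clogp: Mapping[str, float], bin_width: float = 0.5
) -> tuple[pd.DataFrame, float]:
    """Bin metabolites by CLogP; regress mean -logC on mean CLogP over bins.

    Returns the per-bin table (bin, n, mean CLogP, mean -logC) and the R^2
    of the ordinary least-squares line through the bin means. Requires at
    least 3 non-empty bins.
    """
    rows = []
    for r in dataset.records:
        if r.neg_log_c is None:
            continue
        if r.metabolite_id not in clogp:
            raise KeyError(f"CLogP missing for metabolite {r.metabolite_id!r}")
        rows.append((clogp[r.metabolite_id], r.neg_log_c))
    if not rows:
        raise ValueError("no records with -logC available")
    df = pd.DataFrame(rows, columns=["clogp", "neg_log_c"])
    df["bin"] = np.floor(df["clogp"] / bin_width).astype(int)
    table = (
        df.groupby("bin")
        .agg(n=("clogp", "size"), mean_clogp=("clogp", "mean"), mean_neg_log_c=("neg_log_c", "mean"))
        .reset_index()
    )
    if len(table) < 3:
        raise ValueError(f"only {len(table)} non-empty CLogP bin(s); need at least 3")
    fit = stats.linregress(table["mean_clogp"], table["mean_neg_log_c"])
    return table, float(fit.rvalue**2)


def pathway_deviation_table(
    dataset: Dataset, mpf_members: Sequence[str], clogp: Mapping[str, float]
) -> tuple[pd.DataFrame, dict]:
    """Per-member -logC by organism and CLogP, with NA-excluded group means.

    ``mpf_members`` are the metabolite ids belonging to the pathways of
    the MPF descriptor. The summary reports the members' mean -logC per
    organism (missing values excluded), their mean CLogP, and the same
    means over the whole dataset.
    """
    members = list(dict.fromkeys(mpf_members))
    if not members:
        raise ValueError("mpf_members must be non-empty")
    organisms = sorted({r.organism for r in dataset.records})
    by_key = {(r.metabolite_id, r.organism): r for r in dataset.records}
    names = {}
    for r in dataset.records:
        names.setdefault(r.metabolite_id, r.name or r.metabolite_id)
    rows = []
    for mid in members:
        row: dict = {"metabolite_id": mid, "name": names.get(mid, mid)}
        for org in organisms:
            rec = by_key.get((mid, org))
            row[f"neg_log_c_{org}"] = (
                rec.neg_log_c if rec is not None and rec.neg_log_c is not None else np.nan
            )
        row["clogp"] = clogp.get(mid, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = {
        "mean_neg_log_c": {
            org: float(table[f"neg_log_c_{org}"].mean()) for org in organisms
        },
        "n_non_na": {org: int(table[f"neg_log_c_{org}"].notna().sum()) for org in organisms},
        "mean_clogp": float(table["clogp"].mean()),
        "n_members": len(members),
        "dataset_mean_neg_log_c": float(
            np.nanmean([r.neg_log_c if r.neg_log_c is not None else np.nan for r in dataset.records])
        ),
        "dataset_mean_clogp": float(
            np.nanmean([clogp.get(r.metabolite_id, np.nan) for r in dataset.records])
        ),
    }
    return table, summary


def assemble(
    dataset: Dataset,
    molecular: FeatureMatrix,
    topology: Mapping[str, pd.DataFrame] | None = None,
    members: Mapping[str, set[str]] | None = None,
    pathways: set[str] | None = None,
) -> FeatureMatrix:
    """Concatenate molecular, topology and pathway blocks for a dataset.

    ``molecular`` is indexed by metabolite_id (shared across organisms);
    ``topology`` maps organism -> per-node descriptor table
    (``metabolite_id, degree, clustering_coefficient``), so metabolites
    measured in two organisms get organism-specific topology values.
    """
    keys = dataset.row_keys()
    mol = molecular.frame.reindex([r.metabolite_id for r in dataset.records])
    if mol.isna().any().any():
        missing = sorted(set(mol.index[mol.isna().any(axis=1)]))
        raise ValueError(f"molecular descriptors missing for metabolites: {missing[:10]}")
    mol.index = keys
    out = FeatureMatrix(mol, {c: "molecular" for c in mol.columns})

    if topology is not None:
        deg = np.zeros(len(keys))
        cc = np.zeros(len(keys))
        for i, rec in enumerate(dataset.records):
            tab = topology.get(rec.organism)
            if tab is None:
                continue
            hit = tab[tab["metabolite_id"] == rec.metabolite_id]
            if len(hit):
                deg[i] = float(hit["degree"].iloc[0])
                cc[i] = float(hit["clustering_coefficient"].iloc[0])
        topo = pd.DataFrame(
            {"Degree": deg, "Clustering-Coefficient": cc}, index=keys
        )
        out = out.join(FeatureMatrix(topo, {c: "topology" for c in topo.columns}))

    if members is not None and pathways:
        out = out.join(pathway_variables(members, pathways, keys))
    return out
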