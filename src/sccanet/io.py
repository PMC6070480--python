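"""Plain-text interchange formats.

Everything is delimited text so runs are inspectable without special
tooling:

* connectivity stack — long CSV ``subject_id, node_i, node_j, weight`` with
  1-based node ids (upper triangle is enough; the mirror is filled in), or a
  directory of per-subject square CSV matrices;
* clinical CSV — ``subject_id`` plus one column per item;
* covariate CSV — ``subject_id, age, sex, race, motion``;
* community file — ``node_id, node_name, community_label``; its row order
  fixes the canonical node order (ids are 1-based in files, 0-based in
  memory);
* ground-truth sidecar for synthetic cohorts — JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .netmods import CommunityAssignment

logger = logging.getLogger("sccanet")

__all__ = [
    "read_connectivity_stack",
    "write_connectivity_stack",
    "read_clinical",
    "read_covariates",
    "read_communities",
    "write_communities",
    "write_cohort",
    "read_truth",
    "align_subjects",
]


def write_connectivity_stack(path, matrices, subjects) -> None:
    """Write per-subject symmetric matrices as a long upper-triangle CSV."""
    n = np.asarray(matrices[0]).shape[0]
    iu = np.triu_indices(n)
    frames = []
    for label, mat in zip(subjects, matrices):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": label,
                    "node_i": iu[0] + 1,
                    "node_j": iu[1] + 1,
                    "weight": np.asarray(mat)[iu],
                }
            )
        )
    # %.17g keeps write -> read round trips value-exact
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_connectivity_stack(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a connectivity stack; returns ``(matrices, subject_ids)``.

    ``path`` may be a long-format CSV or a directory of per-subject square
    CSV matrices named ``<subject_id>.csv``.  Entries given only for
    ``i <= j`` are mirrored; conflicting asymmetric duplicates raise.
    """
    path = Path(path)
    if path.is_dir():
        mats, subs = [], []
        for f in sorted(path.glob("*.csv")):
            mat = pd.read_csv(f, header=None).to_numpy(dtype=float)
            if mat.shape[0] != mat.shape[1]:
                raise ValueError(f"matrix file {f.name} is not square: {mat.shape}")
            mats.append(mat)
            subs.append(f.stem)
        if not mats:
            raise FileNotFoundError(f"no .csv matrices found in {path}")
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent node counts across subjects: {sorted(shapes)}")
        return np.stack(mats), np.asarray(subs)

    table = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "node_i", "node_j", "weight"}
    if not required.issubset(table.columns):
        raise ValueError(f"connectivity table needs columns {sorted(required)}")
    n_nodes = int(max(table["node_i"].max(), table["node_j"].max()))
    mats, subs = [], []
    expected_pairs = n_nodes * (n_nodes + 1) // 2
    for label, grp in table.groupby("subject_id", sort=True):
        mat = np.full((n_nodes, n_nodes), np.nan)
        i = grp["node_i"].to_numpy(dtype=int) - 1
        j = grp["node_j"].to_numpy(dtype=int) - 1
        w = grp["weight"].to_numpy(dtype=float)
        mat[i, j] = w
        mirror = np.isnan(mat[j, i])
        mat[j[mirror], i[mirror]] = w[mirror]
        if np.isnan(mat).any():
            missing = int(np.isnan(mat[np.triu_indices(n_nodes)]).sum())
            raise ValueError(
                f"subject {label!r} is missing {missing} of {expected_pairs} node pairs"
            )
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError(f"subject {label!r} has conflicting asymmetric entries")
        mats.append(mat)
        subs.append(label)
    return np.stack(mats), np.asarray(subs)


def _read_indexed_csv(path, kind: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "subject_id" not in table.columns:
        raise ValueError(f"{kind} table needs a subject_id column")
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in {kind} table: {dups[:5]}")
    return table.set_index("subject_id")


def read_clinical(path) -> pd.DataFrame:
    """Subjects x items table; every item column must be numeric."""
    table = _read_indexed_csv(path, "clinical")
    for col in table.columns:
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().any():
            row = table.index[coerced.isna()][0]
            raise ValueError(f"non-numeric clinical value at subject {row!r}, item {col!r}")
        table[col] = coerced
    return table


def read_covariates(path) -> pd.DataFrame:
    table = _read_indexed_csv(path, "covariate")
    missing = {"age", "sex", "race", "motion"} - set(table.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    return table


def read_communities(path) -> CommunityAssignment:
    """Node table fixing canonical node order; 1-based ids in the file."""
    table = pd.read_csv(path)
    needed = {"node_id", "community_label"}
    if not needed.issubset(table.columns):
        raise ValueError(f"community file needs columns {sorted(needed)}")
    ids = table["node_id"].to_numpy(dtype=int)
    if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
        raise ValueError("node_id must enumerate 1..n_nodes exactly once")
    table = table.sort_values("node_id")
    names = table["node_name"].tolist() if "node_name" in table.columns else None
    return CommunityAssignment(labels=table["community_label"].to_numpy(), names=names)


def write_communities(path, comm: CommunityAssignment) -> None:
    names = comm.names if comm.names is not None else [f"node_{i + 1}" for i in range(comm.n_nodes)]
    pd.DataFrame(
        {
            "node_id": np.arange(1, comm.n_nodes + 1),
            "node_name": names,
            "community_label": comm.labels,
        }
    ).to_csv(path, index=False)


def align_subjects(
    clinical: pd.DataFrame, covariates: pd.DataFrame, conn_subjects
) -> np.ndarray:
    """Subjects present in all three sources, in connectivity order."""
    conn_subjects = np.asarray(conn_subjects)
    keep = [s for s in conn_subjects if s in clinical.index and s in covariates.index]
    dropped = len(conn_subjects) - len(keep)
    extra = (len(set(clinical.index) - set(keep)) + len(set(covariates.index) - set(keep)))
    if dropped or extra:
        logger.warning(
            "subject alignment: %d connectivity subject(s) dropped, "
            "%d clinical/covariate row(s) unused", dropped, extra,
        )
    if not keep:
        raise ValueError("no subjects shared by connectivity, clinical and covariate tables")
    return np.asarray(keep)


def write_cohort(outdir, cohort) -> dict:
    """Write a synthetic cohort in the standard input formats (+ truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "connectivity": outdir / "connectivity.csv",
        "clinical": outdir / "clinical.csv",
        "covariates": outdir / "covariates.csv",
        "communities": outdir / "communities.csv",
        "truth": outdir / "truth.json",
    }
    write_connectivity_stack(paths["connectivity"], cohort.connectivity, cohort.subjects)
    cohort.clinical.to_csv(paths["clinical"])
    cohort.covariates.to_csv(paths["covariates"])
    write_communities(paths["communities"], CommunityAssignment(cohort.communities))
    truth = cohort.truth
    payload = {
        "seed": cohort.config.seed,
        "u_true": truth.u_true.tolist(),
        "v_true": truth.v_true.tolist(),
        "latent_scores": truth.latent_scores.tolist(),
        "edge_index": truth.edge_index.tolist(),
    }
    paths["truth"].write_text(json.dumps(payload))
    return {k: str(v) for k, v in paths.items()}


def read_truth(path):
    """Load a ground-truth sidecar written by :func:`write_cohort`."""
    from .synthetic import GroundTruth

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        u_true=np.asarray(payload["u_true"]),
        v_true=np.asarray(payload["v_true"]),
        latent_scores=np.asarray(payload["latent_scores"]),
        edge_index=np.asarray(payload["edge_index"], dtype=int),
    )
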