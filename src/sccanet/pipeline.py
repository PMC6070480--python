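"""End-to-end pipeline driver.

``run_pipeline`` executes the full analysis in the canonical order —
prepare (vectorize, MAD filter, residualize, standardize) -> optional
sparsity tuning -> sparse CCA fit -> scree-based variate selection ->
permutation significance -> resampling stability -> network-module
summaries -> cross-dimension common-edge overlap -> age/sex GAMs — and
writes every stage's artifacts as CSV/JSON under the output directory.

Runs carry a role: a *discovery* run may tune the sparsity fractions; a
*replication* run must be given frozen fractions and refuses to re-tune.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, devsex, features, inference, io, netmods, selection
from .scca import CanonicalModel, SccaParams, fit_scca

logger = logging.getLogger("sccanet")

__all__ = ["RunConfig", "ResultBundle", "run_pipeline"]

CONN_CONFOUNDS = ("age", "sex", "race", "motion")
CLIN_CONFOUNDS = ("age", "sex", "race")
#: confounds kept out of the developmental refit (age and sex must remain)
PARTIAL_CONN_CONFOUNDS = ("race", "motion")
PARTIAL_CLIN_CONFOUNDS = ("race",)


@dataclass
class RunConfig:
    connectivity: str
    clinical: str
    covariates: str
    communities: str
    output_dir: str
    mad_fraction: float = 0.1
    c1_frac: float | str = "tune"
    c2_frac: float | str = "tune"
    n_components: int = 7
    n_permutations: int = 1000
    n_resamples: int = 200
    ci_level_u: float = 0.99
    ci_level_v: float = 0.95
    module_permutations: int = 1000
    overlap_permutations: int = 1000
    grid_step: float = 0.1
    tune_draws: int = 10
    seed: int = 0
    role: str = "discovery"
    run_gam: bool = True
    gam_interaction: bool = True

    def __post_init__(self) -> None:
        if self.role not in ("discovery", "replication"):
            raise ValueError(f"role must be discovery or replication, got {self.role!r}")
        wants_tuning = self.c1_frac == "tune" or self.c2_frac == "tune"
        if self.role == "replication" and wants_tuning:
            raise ValueError(
                "replication runs require frozen sparsity fractions; "
                "set c1_frac and c2_frac to the values tuned on the discovery sample"
            )
        for name in ("c1_frac", "c2_frac"):
            val = getattr(self, name)
            if val != "tune" and not 0.0 <= float(val) <= 1.0:
                raise ValueError(f"{name} must be 'tune' or a number in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass
class ResultBundle:
    model: CanonicalModel
    selected: list[int]
    tuning: selection.TuningResult | None
    permutation: inference.PermutationResult
    stability: inference.StabilityResult
    modules: dict
    overlap: netmods.OverlapResult | None
    gam: devsex.GAMResult | None
    feature_matrix: features.FeatureMatrix
    provenance: dict = field(default_factory=dict)


def _prepare(config: RunConfig):
    matrices, conn_subjects = io.read_connectivity_stack(config.connectivity)
    clinical = io.read_clinical(config.clinical)
    covariates = io.read_covariates(config.covariates)
    comm = io.read_communities(config.communities)
    if matrices.shape[1] != comm.n_nodes:
        raise ValueError(
            f"connectivity has {matrices.shape[1]} nodes but community file lists {comm.n_nodes}"
        )
    subjects = io.align_subjects(clinical, covariates, conn_subjects)
    order = {s: k for k, s in enumerate(conn_subjects)}
    matrices = matrices[[order[s] for s in subjects]]
    clinical = clinical.loc[subjects]
    covariates = covariates.loc[subjects]

    fm = features.vectorize_connectivity(matrices, subjects)
    fm = features.filter_by_mad(fm, config.mad_fraction)
    logger.info("retained %d of %d connectivity features", fm.n_features,
                fm.selection_meta["n_enumerated"])
    X = features.standardize(features.residualize(fm.values, covariates, CONN_CONFOUNDS))
    Y = features.standardize(
        features.residualize(clinical.to_numpy(dtype=float), covariates, CLIN_CONFOUNDS)
    )
    X_partial = features.standardize(
        features.residualize(fm.values, covariates, PARTIAL_CONN_CONFOUNDS)
    )
    Y_partial = features.standardize(
        features.residualize(clinical.to_numpy(dtype=float), covariates, PARTIAL_CLIN_CONFOUNDS)
    )
    return fm, clinical, covariates, comm, X, Y, X_partial, Y_partial


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run every stage in order and write artifacts; deterministic per seed."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("tune", "permute", "stabilize", "modules", "overlap"),
            rng.integers(0, 2**31 - 1, size=5),
        )
    }

    logger.info("stage: prepare")
    fm, clinical, covariates, comm, X, Y, X_partial, Y_partial = _prepare(config)

    tuning = None
    c1, c2 = config.c1_frac, config.c2_frac
    if "tune" in (c1, c2):
        logger.info("stage: tune")
        tuning = selection.grid_search(
            X, Y, grid_step=config.grid_step, n_draws=config.tune_draws,
            seed=stage_seeds["tune"],
        )
        c1, c2 = tuning.chosen
        tuning.surface.to_csv(outdir / "tuning_surface.csv", index=False)
    params = SccaParams(c1_frac=float(c1), c2_frac=float(c2),
                        n_components=config.n_components)

    logger.info("stage: fit")
    model = fit_scca(X, Y, params)
    loadings_u = pd.DataFrame(
        model.U, columns=[f"variate_{k}" for k in range(model.n_components)]
    )
    loadings_u.insert(0, "node_i", fm.feature_index[:, 0] + 1)
    loadings_u.insert(1, "node_j", fm.feature_index[:, 1] + 1)
    loadings_u.to_csv(outdir / "connectivity_loadings.csv", index=False)
    loadings_v = pd.DataFrame(
        model.V, columns=[f"variate_{k}" for k in range(model.n_components)]
    )
    loadings_v.insert(0, "item", clinical.columns)
    loadings_v.to_csv(outdir / "clinical_loadings.csv", index=False)

    selected = selection.select_components(model)
    logger.info("selected %d of %d variates: %s", len(selected), model.n_components, selected)

    logger.info("stage: permute (B=%d)", config.n_permutations)
    perm = inference.permutation_test(
        X, Y, params, selected=selected, B=config.n_permutations,
        seed=stage_seeds["permute"], reference=model,
    )
    pd.DataFrame(
        {
            "variate": perm.selected,
            "observed_r": perm.observed_r,
            "p": perm.p,
            "q": perm.q,
        }
    ).to_csv(outdir / "permutation_pvalues.csv", index=False)
    pd.DataFrame(
        perm.null_r, columns=[f"variate_{k}" for k in perm.selected]
    ).to_csv(outdir / "permutation_null_r.csv", index=False)

    logger.info("stage: stabilize (R=%d)", config.n_resamples)
    stab = inference.stability_resample(
        X, Y, params, model, selected=selected, R=config.n_resamples,
        seed=stage_seeds["stabilize"], ci_level_u=config.ci_level_u,
        ci_level_v=config.ci_level_v,
    )
    for axis, idx_cols, lo, hi, sig in (
        ("connectivity", None, stab.u_lo, stab.u_hi, stab.u_significant),
        ("clinical", clinical.columns, stab.v_lo, stab.v_hi, stab.v_significant),
    ):
        frames = []
        for pos, k in enumerate(selected):
            frame = pd.DataFrame(
                {
                    "variate": k,
                    "ci_lower": lo[:, pos],
                    "ci_upper": hi[:, pos],
                    "significant": sig[:, pos],
                }
            )
            if idx_cols is None:
                frame.insert(0, "node_i", fm.feature_index[:, 0] + 1)
                frame.insert(1, "node_j", fm.feature_index[:, 1] + 1)
            else:
                frame.insert(0, "item", idx_cols)
            frames.append(frame)
        pd.concat(frames).to_csv(outdir / f"stability_{axis}.csv", index=False)

    logger.info("stage: modules")
    modules = {}
    masks, load_mats = [], []
    for pos, k in enumerate(selected):
        W = netmods.build_loading_matrix(
            model.U[:, k], fm.feature_index, comm.n_nodes,
            significant_mask=stab.u_significant[:, pos],
        )
        mod = netmods.module_label_permutation(
            W, comm, B=config.module_permutations, seed=stage_seeds["modules"] + k
        )
        modules[k] = mod
        mod.mean_loading.to_csv(outdir / f"module_loading_variate_{k}.csv")
        mod.q.to_csv(outdir / f"module_loading_q_variate_{k}.csv")
        masks.append(W != 0)
        load_mats.append(W)

    overlap = None
    if len(selected) >= 2:
        logger.info("stage: overlap")
        overlap = netmods.common_edge_overlap(
            masks, load_mats, B=config.overlap_permutations, seed=stage_seeds["overlap"]
        )
        ii, jj = np.where(np.triu(overlap.common_edge_mask, k=1))
        pd.DataFrame(
            {
                "node_i": ii + 1,
                "node_j": jj + 1,
                "mean_abs_loading": overlap.mean_abs_loading[ii, jj],
            }
        ).to_csv(outdir / "common_edges.csv", index=False)
        pd.DataFrame(
            {
                "node_id": np.arange(1, comm.n_nodes + 1),
                "strength": overlap.nodal_strength,
            }
        ).to_csv(outdir / "nodal_strength.csv", index=False)

    gam = None
    if config.run_gam:
        logger.info("stage: gam")
        scores = devsex.dimension_scores(X_partial, Y_partial, model, params, selected)
        gam = devsex.fit_age_sex_gam(
            scores,
            covariates["age"].to_numpy(dtype=float),
            covariates["sex"].to_numpy(),
            interaction=config.gam_interaction,
        )
        gam.table.to_csv(outdir / "gam_effects.csv", index=False)

    provenance = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "chosen_sparsity": {"c1_frac": float(c1), "c2_frac": float(c2)},
        "selected_variates": [int(k) for k in selected],
        "stage_seeds": stage_seeds,
        "n_subjects": int(fm.n_subjects),
        "n_features": int(fm.n_features),
        "observed_r": [float(r) for r in model.correlations],
        "covariance_explained": [float(cv.cov_frac) for cv in model.variates],
    }
    (outdir / "run_metadata.json").write_text(json.dumps(provenance, indent=2))
    return ResultBundle(
        model=model, selected=selected, tuning=tuning, permutation=perm,
        stability=stab, modules=modules, overlap=overlap, gam=gam,
        feature_matrix=fm, provenance=provenance,
    )
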