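"""End-to-end orchestration: bin → scale → PCA QC → OPLS-DA (full and
glucose-excluded) → univariate testing → three-criterion selection → report.

The pipeline is deterministic given a config and seed: every output table is
reproducible byte for byte, and figures are rendered from the exported tables
rather than from in-memory state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_profile_matrix, read_spectrum
from .oplsda import ClassVector, cross_validate, fit_oplsda, sline, vip_with_cvse
from .pca import fit_pca, outlier_report
from .preprocess import apply_scaling, fit_scaling
from .regions import ProfileMatrix, RegionTable, bin_dataset, default_region_table, exclude_glucose, load_region_table
from .univar import SelectionCriteria, select_discriminators, univariate_table

__all__ = ["PipelineConfig", "RunReport", "ingest_matrix", "metadata_summary", "run_pipeline", "packaged_subjects_path"]

log = logging.getLogger("nmrprofiler")


@dataclass
class PipelineConfig:
    """All analysis settings; defaults reproduce the study protocol
    (Pareto scaling, 7-fold CV, |p(corr)| > 0.6, VIP > 0.5, glucose-excluded
    rerun enabled)."""

    matrix: str | None = None
    metadata: str | None = None
    spectra_dir: str | None = None
    region_table: str = "default"
    case_label: str = "T1DM"
    control_label: str = "control"
    scaling: str = "pareto"
    pca_components: int = 2
    a_ortho: int = 1
    n_folds: int = 7
    seed: int = 1
    alpha_adj: float = 0.05
    pcorr_min: float = 0.6
    vip_min: float = 0.5
    alpha_outlier: float = 0.05
    vip_mode: str = "predictive"
    rescale_per_fold: bool = True
    run_glucose_excluded: bool = True
    make_figures: bool = True
    out_dir: str = "profiler_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    @property
    def criteria(self) -> SelectionCriteria:
        return SelectionCriteria(self.alpha_adj, self.pcorr_min, self.vip_min)


@dataclass
class RunReport:
    config: PipelineConfig
    summaries: dict = field(default_factory=dict)   # per model variant
    outliers: pd.DataFrame | None = None
    selections: dict = field(default_factory=dict)  # per model variant
    out_dir: Path | None = None


def packaged_subjects_path():
    """Path to the packaged subject-characteristics table (14 matched
    children: 7 T1DM cases, 7 controls; age, sex, Tanner stage, BMI-SDS)."""
    return resources.files("nmrprofiler.data").joinpath("subjects.csv")


def ingest_matrix(matrix_path, metadata_path) -> ProfileMatrix:
    """Load and validate a profile matrix plus its sample metadata.

    Sample ids must match one-to-one, the group column must have exactly two
    levels, and missing values are rejected (no imputation).
    """
    pm = read_profile_matrix(matrix_path, metadata_path)
    if pm.metadata is None or "group" not in pm.metadata:
        raise ValueError("metadata must contain a 'group' column")
    levels = pm.metadata["group"].unique()
    if len(levels) != 2:
        raise ValueError(f"group column must have exactly 2 levels, found {sorted(map(str, levels))}")
    if pm.values.isna().any().any() or pm.metadata.isna().any().any():
        raise ValueError("missing values are not allowed (no imputation is performed)")
    for line in metadata_summary(pm).to_string().splitlines():
        log.info("metadata | %s", line)
    return pm


def metadata_summary(pm: ProfileMatrix) -> pd.DataFrame:
    """Group-wise mean ± SD of the numeric metadata columns (subject-table analog)."""
    if pm.metadata is None:
        raise ValueError("no metadata attached")
    num = pm.metadata.select_dtypes("number")
    if num.shape[1] == 0:
        return pd.DataFrame(index=pd.Index(sorted(pm.metadata["group"].unique()), name="group"))
    agg = num.groupby(pm.metadata["group"]).agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg


def _load_inputs(cfg: PipelineConfig) -> tuple[ProfileMatrix, RegionTable]:
    rt = default_region_table() if cfg.region_table == "default" else load_region_table(cfg.region_table)
    if cfg.matrix is not None:
        if cfg.metadata is None:
            raise ValueError("matrix input requires a metadata file")
        pm = ingest_matrix(cfg.matrix, cfg.metadata)
        expected = [f"var_{v}" for v in rt.var_ids]
        if list(pm.values.columns) != expected:
            raise ValueError("matrix columns do not match the region table")
    elif cfg.spectra_dir is not None:
        paths = sorted(Path(cfg.spectra_dir).glob("*.txt")) + sorted(Path(cfg.spectra_dir).glob("*.tsv"))
        if not paths:
            raise ValueError(f"no spectra found in {cfg.spectra_dir}")
        spectra = [read_spectrum(p) for p in paths]
        ids = [p.stem for p in paths]
        meta = None
        if cfg.metadata is not None:
            meta = pd.read_csv(cfg.metadata, index_col="sample_id")
        pm = bin_dataset(spectra, rt, ids, meta)
    else:
        raise ValueError("config must provide either matrix+metadata or spectra_dir")
    return pm, rt


def _fit_branch(pm: ProfileMatrix, rt: RegionTable, cfg: PipelineConfig, name: str) -> dict:
    """Fit one model variant (full or glucose-excluded) and all its statistics."""
    X = pm.to_array()
    y = ClassVector.from_labels(pm.groups.to_numpy(), positive_label=cfg.control_label)
    params = fit_scaling(X, cfg.scaling, var_ids=pm.var_ids)
    Xs = apply_scaling(X, params)

    model = fit_oplsda(Xs, y, cfg.a_ortho)
    cv = cross_validate(
        X, y, cfg.a_ortho, cfg.n_folds, cfg.seed,
        scaling_mode=cfg.scaling, rescale_per_fold=cfg.rescale_per_fold,
    )
    sl = sline(model, Xs, var_ids=pm.var_ids)
    v, cvse = vip_with_cvse(model, cv, mode=cfg.vip_mode)
    sl["vip"] = v
    sl["vip_cvse"] = cvse

    uni = univariate_table(pm.values, pm.groups, cfg.case_label, cfg.control_label, pm.var_ids)
    sel = select_discriminators(uni, sl, cfg.criteria)
    info = rt.subset(pm.var_ids).to_frame()
    sel = info.merge(sel, on="var_id").sort_values("var_id").reset_index(drop=True)

    scores = pd.DataFrame(
        {"sample_id": pm.sample_ids, "group": pm.groups.to_numpy(), "t_pred": model.t_pred}
    )
    for a in range(model.n_ortho):
        scores[f"t_ortho_{a + 1}"] = model.t_ortho[:, a]

    log.info(
        "%s model: K=%d  R2X(cum)=%.3f  R2Y(cum)=%.3f  Q2(cum)=%.3f  selected=%d",
        name, pm.n_variables, model.r2x_cum, model.r2y_cum, cv.q2_cum, int(sel["selected"].sum()),
    )
    return {
        "name": name,
        "n_variables": pm.n_variables,
        "model": model,
        "cv": cv,
        "selection": sel,
        "scores": scores,
        "summary": {
            "n_variables": pm.n_variables,
            "n_samples": pm.n_samples,
            "a_ortho": model.n_ortho,
            "r2x_cum": model.r2x_cum,
            "r2y_cum": model.r2y_cum,
            "q2_cum": cv.q2_cum,
            "component_r2x": model.component_r2x,
            "n_selected": int(sel["selected"].sum()),
        },
    }


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in fixed order and write all artifacts to out_dir."""
    pm, rt = _load_inputs(cfg)
    n = pm.n_samples
    if cfg.n_folds > n:
        raise ValueError(f"n_folds ({cfg.n_folds}) exceeds sample count ({n})")
    levels = set(pm.groups.unique())
    if levels != {cfg.case_label, cfg.control_label}:
        raise ValueError(
            f"group levels {sorted(map(str, levels))} do not match configured labels "
            f"{cfg.case_label!r}/{cfg.control_label!r}"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("ingested %d samples × %d variables (%s)", n, pm.n_variables, rt.name)

    # --- PCA quality control on the scaled full matrix
    X = pm.to_array()
    params = fit_scaling(X, cfg.scaling, var_ids=pm.var_ids)
    Xs = apply_scaling(X, params)
    pca_model = fit_pca(Xs, cfg.pca_components)
    rep = outlier_report(pca_model, cfg.alpha_outlier)
    outliers = rep.to_frame(pm.sample_ids)
    pca_scores = pd.DataFrame(
        pca_model.scores, columns=[f"pc{a + 1}" for a in range(pca_model.n_components)]
    )
    pca_scores.insert(0, "sample_id", pm.sample_ids)
    # metadata columns exported for confounder staining of the score plot
    if pm.metadata is not None:
        for col in pm.metadata.columns:
            pca_scores[col] = pm.metadata[col].to_numpy()
    log.info(
        "PCA QC: R2X per component %s; %d T2 flags, %d DModX flags",
        np.round(pca_model.r2x, 3).tolist(), int(rep.t2_flag.sum()), int(rep.dmodx_flag.sum()),
    )

    # --- model branches
    branches = [_fit_branch(pm, rt, cfg, "110var" if pm.n_variables == 110 else f"{pm.n_variables}var")]
    if cfg.run_glucose_excluded and rt.n_glucose > 0:
        pm95 = exclude_glucose(pm, rt)
        retained_flags = [r.is_glucose for r in rt.subset(pm95.var_ids)]
        if any(retained_flags):  # column audit: the reduced branch must be glucose-free
            raise AssertionError("glucose-flagged variable leaked into the excluded branch")
        branches.append(_fit_branch(pm95, rt, cfg, f"{pm95.n_variables}var"))

    # --- artifacts
    outliers.to_csv(out / "outliers.csv", index=False)
    pca_scores.to_csv(out / "scores_pca.csv", index=False)
    sline_frames = []
    for b in branches:
        b["selection"].to_csv(out / f"results_{b['name'].removesuffix('var')}.csv", index=False)
        sl = b["selection"][["var_id", "ppm_hi", "ppm_lo", "p_ctr", "p_corr", "vip", "vip_cvse"]].copy()
        sl.insert(0, "model", b["name"])
        sline_frames.append(sl)
    pd.concat(sline_frames).to_csv(out / "sline.csv", index=False)
    branches[0]["scores"].to_csv(out / "scores_oplsda.csv", index=False)

    summary = {
        "package": {"name": "nmrprofiler", "version": __version__},
        "config": asdict(cfg),
        "conventions": {
            "class_coding": {cfg.control_label: 1, cfg.case_label: -1},
            "scaling": cfg.scaling,
            "sd_denominator": "n-1",
            "vip_mode": cfg.vip_mode,
            "cvse": "jack-knife over CV submodels",
            "sline_space": "Pareto-scaled variables",
            "t2_limit": "A(N^2-1)/(N(N-A)) * F(1-alpha; A, N-A)",
            "dmodx_limit": "sqrt(F(1-alpha; K-A, (N-A-1)(K-A)))",
        },
        "pca": {
            "n_components": pca_model.n_components,
            "r2x_per_component": pca_model.r2x.tolist(),
            "r2x_cum": pca_model.r2x_cum,
            "n_t2_flags": int(rep.t2_flag.sum()),
            "n_dmodx_flags": int(rep.dmodx_flag.sum()),
        },
        "models": {b["name"]: b["summary"] for b in branches},
        "metadata_summary": json.loads(metadata_summary(pm).to_json()) if pm.metadata is not None and not pm.metadata.select_dtypes("number").empty else None,
    }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    if cfg.make_figures:
        _render_figures(out)

    return RunReport(
        config=cfg,
        summaries={b["name"]: b["summary"] for b in branches},
        outliers=outliers,
        selections={b["name"]: b["selection"] for b in branches},
        out_dir=out,
    )


def _render_figures(out: Path) -> None:
    """Render score, S-line, and DModX plots from the exported tables only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    pca_scores = pd.read_csv(out / "scores_pca.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in pca_scores.groupby("group"):
        ax.scatter(sub["pc1"], sub["pc2"], label=str(grp))
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    ax.set_title("PCA score plot")
    fig.tight_layout()
    fig.savefig(figdir / "scores_pca.png", dpi=150)
    plt.close(fig)

    op = pd.read_csv(out / "scores_oplsda.csv")
    if "t_ortho_1" in op.columns:
        fig, ax = plt.subplots(figsize=(5, 4))
        for grp, sub in op.groupby("group"):
            ax.scatter(sub["t_pred"], sub["t_ortho_1"], label=str(grp))
        ax.set_xlabel("t[1]P (predictive)")
        ax.set_ylabel("t[1]O (orthogonal)")
        ax.legend()
        ax.set_title("OPLS-DA score plot")
        fig.tight_layout()
        fig.savefig(figdir / "scores_oplsda.png", dpi=150)
        plt.close(fig)

    sl = pd.read_csv(out / "sline.csv")
    for model_name, sub in sl.groupby("model"):
        fig, ax = plt.subplots(figsize=(7, 4))
        centers = (sub["ppm_hi"] + sub["ppm_lo"]) / 2
        sc = ax.scatter(centers, sub["p_ctr"], c=sub["p_corr"].abs(), cmap="coolwarm", s=12)
        fig.colorbar(sc, ax=ax, label="|p(corr)[1]|")
        ax.invert_xaxis()
        ax.set_xlabel("ppm")
        ax.set_ylabel("p(ctr)[1]")
        ax.set_title(f"S-line ({model_name})")
        fig.tight_layout()
        fig.savefig(figdir / f"sline_{model_name}.png", dpi=150)
        plt.close(fig)

    outliers = pd.read_csv(out / "outliers.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(outliers["sample_id"], outliers["dmodx"])
    ax.axhline(outliers["dmodx_limit"].iloc[0], color="red", ls="--", label="D-crit")
    ax.set_ylabel("DModX")
    ax.tick_params(axis="x", rotation=90)
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "dmodx.png", dpi=150)
    plt.close(fig)
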