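"""Seedable two-group synthetic data with the study's printed effect structure.

The generator draws region integrals from a log-normal model: for each group
a multivariate normal is sampled on the log scale (with optional block
correlation between variables belonging to the same metabolite) and
exponentiated, guaranteeing positive integrals with the right-skew typical of
plasma NMR intensities.  Log-scale means/variances are moment-matched so that
the *arithmetic* mean and SD of each variable equal the template values —
the template therefore reads exactly like a published group-summary table.

The default template carries the 17 published case/control means ± SDs
(glucose regions up ~23–68% in cases, lipids down ~17–36%, serine/tryptophan/
cysteine down ~25–64%) and null effects (case = control) for the 93
unpublished variables, whose baseline means are synthetic stand-ins drawn
once from a log-uniform range.

Full spectra can additionally be rendered from a profile (one Lorentzian per
region, truncated at the region bounds, plus optional white noise) so the
binning stage itself is exercisable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from . import _defaults
from .regions import ProfileMatrix, RegionTable, Spectrum, _region_integral, default_region_table

__all__ = [
    "CorrelationBlock",
    "EffectTemplate",
    "SyntheticDataset",
    "default_template",
    "load_template",
    "generate_profiles",
    "generate_spectra",
    "CASE_LABEL",
    "CONTROL_LABEL",
]

CASE_LABEL = "T1DM"
CONTROL_LABEL = "control"
# y coding for downstream discriminant analysis: controls positive, cases negative
CLASS_CODE = {CONTROL_LABEL: +1.0, CASE_LABEL: -1.0}


@dataclass(frozen=True)
class CorrelationBlock:
    """Variables sharing a common intra-block log-scale correlation rho."""

    name: str
    var_ids: tuple[int, ...]
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 0.95):
            raise ValueError(f"block {self.name}: rho must be in [0, 0.95], got {self.rho}")
        if len(set(self.var_ids)) != len(self.var_ids):
            raise ValueError(f"block {self.name}: duplicate var_ids")


@dataclass
class EffectTemplate:
    """Per-variable group means/SDs plus optional correlation blocks."""

    frame: pd.DataFrame  # columns var_id, mean_case, sd_case, mean_control, sd_control
    blocks: tuple[CorrelationBlock, ...] = ()
    name: str = "custom"

    def __post_init__(self) -> None:
        need = ["var_id", "mean_case", "sd_case", "mean_control", "sd_control"]
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise ValueError(f"template missing columns: {missing}")
        f = self.frame
        if f["var_id"].duplicated().any():
            dup = f.loc[f["var_id"].duplicated(), "var_id"].tolist()
            raise ValueError(f"duplicate var_ids in template: {dup}")
        for col in need[1:]:
            bad = f.loc[f[col] <= 0, "var_id"].tolist()
            if bad:
                raise ValueError(f"template column {col} must be > 0; offending var_ids {bad}")
        block_ids = set()
        for b in self.blocks:
            unknown = set(b.var_ids) - set(f["var_id"])
            if unknown:
                raise ValueError(f"block {b.name} references unknown var_ids {sorted(unknown)}")
            if block_ids & set(b.var_ids):
                raise ValueError("correlation blocks must be disjoint")
            block_ids |= set(b.var_ids)
        self.frame = f.reset_index(drop=True)

    @property
    def var_ids(self) -> list[int]:
        return self.frame["var_id"].astype(int).tolist()

    @property
    def n_variables(self) -> int:
        return len(self.frame)

    def is_null(self) -> bool:
        return bool(
            np.allclose(self.frame["mean_case"], self.frame["mean_control"])
            and np.allclose(self.frame["sd_case"], self.frame["sd_control"])
        )

    def as_null(self) -> "EffectTemplate":
        """Copy with case parameters set to control parameters (no group effect)."""
        f = self.frame.copy()
        f["mean_case"] = f["mean_control"]
        f["sd_case"] = f["sd_control"]
        return EffectTemplate(f, self.blocks, name=f"{self.name}-null")


@dataclass
class SyntheticDataset:
    profile: ProfileMatrix
    truth: EffectTemplate
    seed: int

    @property
    def y(self) -> np.ndarray:
        """Class code per row: control +1, case −1."""
        return self.profile.groups.map(CLASS_CODE).to_numpy(dtype=float)


def default_template(region_table: RegionTable | None = None) -> EffectTemplate:
    """The packaged 110-variable template.

    Glucose-flagged variables form one correlation block (rho=0.8), the
    published lipid variables another (rho=0.6).
    """
    rt = region_table or default_region_table()
    frame = _load_template_frame()
    blocks = (
        CorrelationBlock("glucose", tuple(rt.glucose_var_ids), _defaults.GLUCOSE_BLOCK_RHO),
        CorrelationBlock("lipid", tuple(_defaults.LIPID_VAR_IDS), _defaults.LIPID_BLOCK_RHO),
    )
    return EffectTemplate(frame, blocks, name="default-110")


def _load_template_frame() -> pd.DataFrame:
    ref = resources.files("nmrprofiler.data").joinpath("template_110_synthetic.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_template(path, blocks: Sequence[CorrelationBlock] = (), name: str | None = None) -> EffectTemplate:
    """Load an effect template from CSV (columns mirroring EffectTemplate)."""
    return EffectTemplate(pd.read_csv(path), tuple(blocks), name=name or str(path))


# ---------------------------------------------------------------------------
# profile generation

def _lognormal_params(mean: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-scale (mu, sigma) matching arithmetic mean and SD exactly."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _correlation_cholesky(template: EffectTemplate) -> np.ndarray:
    k = template.n_variables
    idx = {v: i for i, v in enumerate(template.var_ids)}
    corr = np.eye(k)
    for b in template.blocks:
        ii = [idx[v] for v in b.var_ids]
        for a in ii:
            for c in ii:
                if a != c:
                    corr[a, c] = b.rho
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation block structure is not positive definite") from e


def _draw_group(rng: np.random.Generator, n: int, mean, sd, chol: np.ndarray) -> np.ndarray:
    mu, sigma = _lognormal_params(np.asarray(mean, float), np.asarray(sd, float))
    z = rng.standard_normal((n, len(mu)))
    log_x = mu + (z @ chol.T) * sigma
    return np.exp(log_x)


def generate_profiles(
    template: EffectTemplate,
    n_case: int = 7,
    n_control: int = 7,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw a two-group profile matrix from the template.

    One seed stream is split deterministically by purpose (case draws,
    control draws, row shuffle), so regeneration with the same seed is
    bit-identical and adding downstream noise never perturbs group draws.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 samples per group")
    ss_case, ss_ctrl, ss_shuf = np.random.SeedSequence(seed).spawn(3)
    chol = _correlation_cholesky(template)
    f = template.frame
    x_case = _draw_group(np.random.default_rng(ss_case), n_case, f["mean_case"], f["sd_case"], chol)
    x_ctrl = _draw_group(np.random.default_rng(ss_ctrl), n_control, f["mean_control"], f["sd_control"], chol)

    ids = [f"case_{i + 1}" for i in range(n_case)] + [f"control_{i + 1}" for i in range(n_control)]
    groups = [CASE_LABEL] * n_case + [CONTROL_LABEL] * n_control
    x = np.vstack([x_case, x_ctrl])
    order = np.random.default_rng(ss_shuf).permutation(len(ids))
    values = pd.DataFrame(
        x[order],
        index=pd.Index([ids[i] for i in order], name="sample_id"),
        columns=[f"var_{v}" for v in template.var_ids],
    )
    meta = pd.DataFrame({"group": [groups[i] for i in order]}, index=values.index)
    return SyntheticDataset(ProfileMatrix(values, meta, template.var_ids), template, seed)


# ---------------------------------------------------------------------------
# spectrum rendering

def generate_spectra(
    dataset: SyntheticDataset,
    table: RegionTable,
    seed: int = 0,
    snr: float | None = None,
    step: float = 0.001,
    margin: float = 0.1,
) -> list[Spectrum]:
    """Render one spectrum per profile row.

    Each region's integral is realized as a single Lorentzian peak centered
    mid-region with half-width 20% of the region width, truncated at the
    region bounds and scaled so its within-region trapezoidal integral equals
    the profile value (peak overlap between regions is deliberately not
    simulated).  ``snr`` adds white Gaussian noise with SD = (max peak
    amplitude)/snr; None means noise-free.
    """
    if dataset.profile.var_ids != table.var_ids:
        raise ValueError("profile columns do not align with region table")
    hi = max(r.ppm_hi for r in table) + margin
    lo = min(r.ppm_lo for r in table) - margin
    ppm_desc = np.arange(hi, lo - step / 2, -step)
    ppm_asc = ppm_desc[::-1]

    # unit-amplitude truncated Lorentzian per region, pre-integrated once;
    # the value at the region edge is subtracted so the peak goes continuously
    # to zero at the boundary (no step to leak into the adjacent region)
    shapes = []
    for r in table:
        center = (r.ppm_hi + r.ppm_lo) / 2.0
        gamma = 0.2 * r.width
        inside = (ppm_asc >= r.ppm_lo) & (ppm_asc <= r.ppm_hi)
        edge = gamma**2 / (gamma**2 + (r.width / 2.0) ** 2)
        shape = np.zeros_like(ppm_asc)
        shape[inside] = gamma**2 / (gamma**2 + (ppm_asc[inside] - center) ** 2) - edge
        unit_integral = _region_integral(ppm_asc, shape, r.ppm_lo, r.ppm_hi)
        shapes.append((shape, unit_integral))

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    x = dataset.profile.to_array()
    spectra = []
    for i in range(x.shape[0]):
        inten = np.zeros_like(ppm_asc)
        for k, (shape, unit) in enumerate(shapes):
            inten += (x[i, k] / unit) * shape
        if snr is not None:
            peak = float(np.max(np.abs(inten)))
            noise_sd = peak / snr if peak > 0 else 1.0 / snr
            inten = inten + rng.normal(0.0, noise_sd, size=inten.shape)
        spectra.append(Spectrum(ppm_asc.copy(), inten))
    return spectra
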