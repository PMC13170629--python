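"""Synthetic cohort generator.

Emulates a two-group study of acute anorexia nervosa (AN) versus healthy
controls (HC): serum neurofilament light (NF-L, a marker of axonal damage)
elevated in AN, plasma leptin depressed in AN with left-censoring at the
assay's lower limit of detection, regional white-matter (WM) volumes with a
planted negative log-NF-L slope, and structural connectomes with planted
components whose fractional anisotropy (FA) tracks NF-L and transmits part
of the leptin-NF-L association (a known mediation structure).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so every generator is reproducible and independently streamable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "generate_cohort",
    "generate_roi_volumes",
    "generate_connectomes",
    "wm_roi_labels",
    "parcellation_labels",
    "DEFAULT_AFFECTED_ROIS",
]

# Desikan-Killiany cortical parcels (34 per hemisphere)
_DK_LABELS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
]

_SUBCORTICAL = [
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area",
]

# ROIs carrying the planted NF-L -> volume slope; the aggregate columns
# inherit the effect through summation.
DEFAULT_AFFECTED_ROIS = [
    "lh-fusiform", "lh-paracentral", "lh-precentral", "lh-superiorfrontal",
    "rh-caudalmiddlefrontal", "rh-fusiform", "rh-inferiortemporal",
    "rh-precuneus", "rh-superiorfrontal",
]


def wm_roi_labels() -> list[str]:
    """The 73 white-matter ROI column labels of the volume table.

    35 regional labels per hemisphere (34 Desikan-Killiany gyral WM parcels
    plus unsegmented WM, as in FreeSurfer's wmparc), the two hemispheric
    cortical WM totals, and the global cortical WM total.
    """
    regional = [f"{h}-{r}" for h in ("lh", "rh")
                for r in _DK_LABELS + ["unsegmentedwhitematter"]]
    return regional + ["lh-CorticalWhiteMatter", "rh-CorticalWhiteMatter",
                       "CorticalWhiteMatter"]


def parcellation_labels(n_nodes: int = 233) -> list[str]:
    """Node labels for the connectome parcellation fixture.

    The conformance fixture subdivides the 34 Desikan-Killiany parcels per
    hemisphere into 219 cortical subregions (110 left, 109 right) and adds
    14 subcortical nuclei (7 per hemisphere), giving 233 nodes. Smaller
    ``n_nodes`` truncates the list (fast-test scale); larger values cycle
    additional subdivisions.
    """
    cortical: list[str] = []
    counts = {"lh": 110, "rh": 109}
    for hemi, n_c in counts.items():
        base, extra = divmod(n_c, len(_DK_LABELS))
        for i, lab in enumerate(_DK_LABELS):
            k = base + (1 if i < extra else 0)
            cortical.extend(f"ctx-{hemi}-{lab}_{j + 1}" for j in range(k))
    sub = [f"{side}-{s}" for side in ("Left", "Right") for s in _SUBCORTICAL]
    labels = cortical + sub
    if n_nodes <= len(labels):
        return labels[:n_nodes]
    reps = [f"{labels[i % len(labels)]}_x{i // len(labels)}"
            for i in range(len(labels), n_nodes)]
    return labels + reps


@dataclass
class GroupParams:
    """Per-group marginal distribution parameters.

    Log-normal markers are parameterized by median and IQR bounds on the
    raw scale; Gaussian variables by median and IQR bounds directly.
    """
    nfl_median: float
    nfl_iqr: tuple[float, float]
    leptin_median: float
    leptin_iqr: tuple[float, float]
    age_median: float
    age_iqr: tuple[float, float]
    bmi_median: float
    bmi_iqr: tuple[float, float]
    bmi_sds_median: float
    bmi_sds_iqr: tuple[float, float]
    edi_dt_median: float
    edi_dt_iqr: tuple[float, float]
    edi_bd_median: float
    edi_bd_iqr: tuple[float, float]
    bdi2_median: float
    bdi2_iqr: tuple[float, float]
    motion_scale: float


# IQR of a Normal spans 2*0.6745 sigma.
_IQR_TO_SD = 1.0 / (2.0 * 0.674489750196082)


def _lognorm_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    mu = np.log(median)
    sigma = (np.log(iqr[1]) - np.log(iqr[0])) * _IQR_TO_SD
    return mu, sigma


def _norm_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    return median, (iqr[1] - iqr[0]) * _IQR_TO_SD


def _default_group_params() -> dict[str, GroupParams]:
    return {
        "AN": GroupParams(
            nfl_median=10.80, nfl_iqr=(7.83, 15.50),
            leptin_median=0.58, leptin_iqr=(0.165, 1.635),
            age_median=15.7, age_iqr=(14.3, 17.2),
            bmi_median=14.77, bmi_iqr=(13.94, 15.71),
            bmi_sds_median=-2.73, bmi_sds_iqr=(-3.64, -2.22),
            edi_dt_median=30, edi_dt_iqr=(22, 36),
            edi_bd_median=37, edi_bd_iqr=(28.75, 45.0),
            bdi2_median=21, bdi2_iqr=(15, 30),
            motion_scale=0.35,
        ),
        "HC": GroupParams(
            nfl_median=5.98, nfl_iqr=(4.73, 7.79),
            leptin_median=10.4, leptin_iqr=(5.895, 15.035),
            age_median=17.0, age_iqr=(15.1, 18.5),
            bmi_median=20.35, bmi_iqr=(19.56, 21.86),
            bmi_sds_median=-0.18, bmi_sds_iqr=(-0.61, 0.27),
            edi_dt_median=13, edi_dt_iqr=(8, 16),
            edi_bd_median=20, edi_bd_iqr=(16, 26),
            bdi2_median=3, bdi2_iqr=(1, 7),
            motion_scale=0.30,
        ),
    }


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort.

    Mediation path coefficients are on standardized latent scales:
    ``path_a`` (leptin -> component connectivity), ``path_b``
    (connectivity -> NF-L) and ``path_c_prime`` (direct leptin -> NF-L),
    active in the AN group only. True standardized indirect effect is
    ``path_a * path_b`` and total is ``path_c_prime + path_a * path_b``.
    """
    n_per_group: int = 77
    seed: int = 0
    lod: float = 0.20
    group_params: dict[str, GroupParams] = field(default_factory=_default_group_params)
    volume_slope: float = -800.0          # mm^3 per unit log-NF-L, affected ROIs
    volume_noise_sd: float = 400.0        # mm^3
    edge_effect: float = 0.02             # FA units per SD of log-NF-L
    path_a: float = -0.5
    path_b: float = 0.45
    path_c_prime: float = -0.45

    def validate(self) -> None:
        if self.n_per_group < 4:
            raise ValueError("CohortConfig.n_per_group must be >= 4")
        if not self.lod > 0:
            raise ValueError("CohortConfig.lod must be > 0")
        if self.volume_noise_sd < 0:
            raise ValueError("CohortConfig.volume_noise_sd must be >= 0")
        for g, p in self.group_params.items():
            for name in ("nfl", "leptin"):
                med = getattr(p, f"{name}_median")
                lo, hi = getattr(p, f"{name}_iqr")
                if not (med > 0 and 0 < lo < hi):
                    raise ValueError(
                        f"CohortConfig.group_params[{g!r}].{name}: median and "
                        "IQR bounds must be positive and increasing")
            if p.motion_scale <= 0:
                raise ValueError(
                    f"CohortConfig.group_params[{g!r}].motion_scale must be > 0")
        resid = 1.0 - self.path_c_prime**2 - self.path_b**2 \
            - 2.0 * self.path_a * self.path_b * self.path_c_prime
        if resid < 0:
            raise ValueError(
                "CohortConfig mediation paths imply latent NF-L variance > 1; "
                "shrink path_a/path_b/path_c_prime")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        import yaml
        d = asdict(self)
        for g, p in d["group_params"].items():
            d["group_params"][g] = {k: list(v) if isinstance(v, tuple)
                                    else v for k, v in p.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "group_params" in raw:
            raw["group_params"] = {
                g: GroupParams(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in p.items()})
                for g, p in raw["group_params"].items()}
        return cls(**raw)


@dataclass
class ParticipantRecord:
    """One subject's group label, biomarkers, covariates and scores."""
    id: str
    group: str
    age: float
    bmi: float
    bmi_sds: float
    nfl: float
    log_nfl: float
    leptin: float
    leptin_censored: bool
    motion: float
    etiv: float
    edi_dt: float
    edi_bd: float
    bdi2: float
    illness_duration: float | None = None


_COHORT_COLUMNS = [
    "id", "group", "age", "bmi", "bmi_sds", "nfl", "log_nfl", "leptin",
    "leptin_censored", "motion", "etiv", "edi_dt", "edi_bd", "bdi2",
    "illness_duration",
]


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a two-group cohort as a participant table.

    Returns a DataFrame with one row per participant (columns of
    :class:`ParticipantRecord`, plus internal latent columns ``z_leptin``
    and ``conn_latent`` consumed by :func:`generate_connectomes`).
    NF-L is log-normal per group; leptin is log-normal per group and
    left-censored at ``config.lod`` by truncation-and-flag. In the AN group
    the latent chain z_leptin -> conn_latent -> z_NFL (plus a direct path)
    plants a partial mediation with known standardized effects.
    """
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    frames = []
    for group, child in zip(("AN", "HC"), ss.spawn(2)):
        rng = np.random.default_rng(child)
        p = config.group_params[group]
        n = config.n_per_group

        z_lep = rng.standard_normal(n)
        if group == "AN":
            a, b, c = config.path_a, config.path_b, config.path_c_prime
            z_conn = a * z_lep + np.sqrt(1.0 - a**2) * rng.standard_normal(n)
            resid_sd = np.sqrt(1.0 - c**2 - b**2 - 2.0 * a * b * c)
            z_nfl = c * z_lep + b * z_conn + resid_sd * rng.standard_normal(n)
        else:
            z_conn = rng.standard_normal(n)
            z_nfl = rng.standard_normal(n)

        mu_l, sd_l = _lognorm_params(p.leptin_median, p.leptin_iqr)
        leptin = np.exp(mu_l + sd_l * z_lep)
        censored = leptin < config.lod
        leptin = np.where(censored, config.lod, leptin)

        mu_n, sd_n = _lognorm_params(p.nfl_median, p.nfl_iqr)
        nfl = np.exp(mu_n + sd_n * z_nfl)

        def gauss(name, lo=None):
            m, s = _norm_params(getattr(p, f"{name}_median"),
                                getattr(p, f"{name}_iqr"))
            v = rng.normal(m, s, n)
            return v if lo is None else np.maximum(v, lo)

        age = gauss("age", lo=12.0)
        bmi = gauss("bmi", lo=10.0)
        bmi_sds = gauss("bmi_sds")
        edi_dt = gauss("edi_dt", lo=0.0)
        edi_bd = gauss("edi_bd", lo=0.0)
        bdi2 = gauss("bdi2", lo=0.0)
        motion = np.abs(rng.normal(0.0, p.motion_scale, n))
        etiv = np.maximum(rng.normal(1.5e6, 1.2e5, n), 1e5)
        if group == "AN":
            dur = np.exp(rng.normal(np.log(12.0), 0.8, n))  # months
        else:
            dur = np.full(n, np.nan)

        frames.append(pd.DataFrame({
            "id": [f"{group}{i + 1:03d}" for i in range(n)],
            "group": group,
            "age": age, "bmi": bmi, "bmi_sds": bmi_sds,
            "nfl": nfl, "log_nfl": np.log(nfl),
            "leptin": leptin, "leptin_censored": censored,
            "motion": motion, "etiv": etiv,
            "edi_dt": edi_dt, "edi_bd": edi_bd, "bdi2": bdi2,
            "illness_duration": dur,
            "z_leptin": z_lep, "conn_latent": z_conn,
        }))
    return pd.concat(frames, ignore_index=True)


def cohort_records(cohort: pd.DataFrame) -> list[ParticipantRecord]:
    """View a cohort table as typed records (latent columns dropped)."""
    recs = []
    for _, row in cohort.iterrows():
        d = {k: row[k] for k in _COHORT_COLUMNS}
        if pd.isna(d["illness_duration"]):
            d["illness_duration"] = None
        recs.append(ParticipantRecord(**d))
    return recs


def generate_roi_volumes(
    cohort: pd.DataFrame,
    slope: float = -800.0,
    noise_sd: float = 400.0,
    seed: int = 0,
    affected_rois: list[str] | None = None,
    group_specific: bool = True,
    age_coef: float = 40.0,
    etiv_coef: float = 0.004,
    baseline: float = 8000.0,
) -> pd.DataFrame:
    """Generate the 73-column WM ROI volume table (mm^3).

    Regional volume = baseline + slope*log_nfl (affected ROIs; AN only when
    ``group_specific``) + age_coef*age + etiv_coef*etiv + noise. The
    hemispheric totals are sums of their 35 regional parts and the global
    column is the sum of the two hemispheric totals, so the planted effect
    propagates into the aggregates.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if affected_rois is None:
        affected_rois = DEFAULT_AFFECTED_ROIS
    labels = wm_roi_labels()
    regional = [c for c in labels if not c.endswith("CorticalWhiteMatter")]
    unknown = set(affected_rois) - set(regional)
    if unknown:
        raise ValueError(f"affected_rois not in fixture labels: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(cohort)
    base_mean = baseline + age_coef * cohort["age"].to_numpy() \
        + etiv_coef * cohort["etiv"].to_numpy()
    active = np.ones(n) if not group_specific \
        else (cohort["group"] == "AN").to_numpy(float)
    vols = pd.DataFrame(index=cohort["id"], columns=labels, dtype=float)
    for roi in regional:
        v = base_mean + rng.normal(0.0, noise_sd, n) if noise_sd > 0 \
            else base_mean.copy()
        if roi in affected_rois:
            v = v + slope * cohort["log_nfl"].to_numpy() * active
        vols[roi] = np.maximum(v, 1.0)
    for hemi in ("lh", "rh"):
        parts = [c for c in regional if c.startswith(f"{hemi}-")]
        vols[f"{hemi}-CorticalWhiteMatter"] = vols[parts].sum(axis=1)
    vols["CorticalWhiteMatter"] = (vols["lh-CorticalWhiteMatter"]
                                   + vols["rh-CorticalWhiteMatter"])
    return vols


def _edge_index(component: list[tuple[int, int]], n_nodes: int) -> np.ndarray:
    idx = np.asarray(component, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_nodes):
        raise ValueError("planted component node index out of range")
    if idx.size and (idx[:, 0] == idx[:, 1]).any():
        raise ValueError("planted component contains a self-loop")
    return idx


def generate_connectomes(
    cohort: pd.DataFrame,
    n_nodes: int = 60,
    planted_components: list[list[tuple[int, int]]] | None = None,
    edge_effect: float = 0.02,
    mediation_components: list[list[tuple[int, int]]] | None = None,
    mediation_edge_effect: float = 0.03,
    seed: int = 0,
    fa_noise: float = 0.03,
    density: float = 0.30,
    group_specific: bool = True,
    labels: list[str] | None = None,
) -> dict[str, dict[str, ConnectivityMatrix]]:
    """Generate per-participant (FA, NOS) connectivity matrix pairs.

    A shared binary support mask (edge density ``density``) and shared
    per-edge FA baselines in [0.3, 0.6] are drawn once; each participant
    adds Gaussian noise. On ``planted_components`` edges, FA gains
    ``edge_effect`` per SD of log-NF-L; on ``mediation_components`` edges,
    FA gains ``mediation_edge_effect`` per unit of the cohort's
    ``conn_latent`` (the leptin-driven latent), realizing the planted
    leptin -> connectivity -> NF-L chain. Effects apply in AN only when
    ``group_specific``. FA is clipped to [0, 1]; NOS are over-dispersed
    counts (gamma-Poisson) on the same support.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    planted = [_edge_index(c, n_nodes) for c in (planted_components or [])]
    mediated = [_edge_index(c, n_nodes) for c in (mediation_components or [])]
    if labels is None:
        labels = parcellation_labels(n_nodes)
    if len(labels) != n_nodes:
        raise ValueError("labels length must equal n_nodes")

    ss = np.random.SeedSequence(seed)
    rng_shared, rng_part = (np.random.default_rng(c) for c in ss.spawn(2))

    iu = np.triu_indices(n_nodes, k=1)
    n_edges = iu[0].size
    support = rng_shared.random(n_edges) < density
    fa_base = rng_shared.uniform(0.30, 0.60, n_edges)
    nos_base = rng_shared.gamma(2.0, 40.0, n_edges)  # mean edge streamline count

    lin = np.zeros((n_nodes, n_nodes), dtype=int)
    lin[iu] = np.arange(n_edges)
    lin = lin + lin.T

    def flat(comps):
        if not comps:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(
            [lin[c[:, 0], c[:, 1]] for c in comps if c.size]))

    planted_idx, mediated_idx = flat(planted), flat(mediated)
    support[planted_idx] = True
    support[mediated_idx] = True

    # standardize log NF-L within the group carrying the effect, so
    # edge_effect is an FA shift per within-group SD of log NF-L
    lognfl = cohort["log_nfl"].to_numpy()
    if group_specific:
        z_nfl = np.zeros(len(cohort))
        for g in cohort["group"].unique():
            sel = (cohort["group"] == g).to_numpy()
            z_nfl[sel] = (lognfl[sel] - lognfl[sel].mean()) \
                / lognfl[sel].std(ddof=0)
    else:
        z_nfl = (lognfl - lognfl.mean()) / lognfl.std(ddof=0)
    z_conn = cohort["conn_latent"].to_numpy() if "conn_latent" in cohort \
        else np.zeros(len(cohort))
    active = np.ones(len(cohort)) if not group_specific \
        else (cohort["group"] == "AN").to_numpy(float)

    out: dict[str, dict[str, ConnectivityMatrix]] = {}
    n_clipped = 0
    n_draws = 0
    for i, pid in enumerate(cohort["id"]):
        fa = np.where(support, fa_base, 0.0).copy()
        if fa_noise > 0:
            fa[support] += rng_part.normal(0.0, fa_noise, support.sum())
        fa[planted_idx] += edge_effect * z_nfl[i] * active[i]
        fa[mediated_idx] += mediation_edge_effect * z_conn[i] * active[i]
        n_draws += support.sum()
        n_clipped += int(((fa < 0) | (fa > 1))[support].sum())
        fa = np.clip(fa, 0.0, 1.0)

        nos = np.zeros(n_edges)
        lam = rng_part.gamma(4.0, nos_base[support] / 4.0)  # over-dispersion
        nos[support] = rng_part.poisson(lam)

        def to_mat(vals, kind):
            m = np.zeros((n_nodes, n_nodes))
            m[iu] = vals
            m = m + m.T
            return ConnectivityMatrix(m, weight_kind=kind, labels=labels)

        out[pid] = {"FA": to_mat(fa, "FA"), "NOS": to_mat(nos, "NOS")}
    if n_draws and n_clipped / n_draws > 0.10:
        logger.warning("FA clipping affected %.1f%% of generated edge values",
                       100.0 * n_clipped / n_draws)
    return out
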