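"""Full study orchestration: repeated noise injection, rates, ANOVA, Scheffe.

The design: threshold the original dataset with all five correction
conditions to get per-method reference maps; then, for each of
``n_repetitions`` (default 10), inject fresh spatially-autocorrelated noise
scaled to the mean contrast strength, re-threshold with all five
conditions, and score each method's noisy map against its own reference
with the false-alarm and hit rates.  Methods are then compared with a
one-way fixed-effects ANOVA per metric and Scheffe post-hoc grouping
letters (methods not significantly different share a letter).

Two choices isolate the injected noise as the only manipulated factor:
per-method permutation seeds are held fixed between the original run and
every noisy run, and (by default) the Monte-Carlo cluster-extent
calibrations of the two simulation-based conditions are computed once on
the original data and reused across repetitions.  Both are configurable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import image_io
from .acf_noise import (
    ACFParams,
    NoiseInjectionConfig,
    dataset_residual_acf,
    inject_noise,
    smoothness_fwhm_from_b,
)
from .consistency import ConsistencyRecord, false_alarm_rate, hit_rate
from .image_io import BrainMask, SubjectDataset, write_volume, ContrastImage
from .synthetic_data import preset_moral, preset_wm, simulate_dataset
from .thresholding import (
    METHOD_NAMES,
    ThresholdConfig,
    ThresholdResult,
    clustsim_threshold,
    derive_seed,
    mc_cluster_threshold,
    run_all_methods,
    snpm_clusterwise,
    snpm_voxelwise,
    tfce_fwe,
)

__all__ = [
    "EvaluationConfig",
    "AnovaResult",
    "run_evaluation",
    "anova_consistency",
    "scheffe_posthoc",
    "report",
]

logger = logging.getLogger(__name__)

_PRESETS = {"moral": preset_moral, "wm": preset_wm}


@dataclass(frozen=True)
class EvaluationConfig:
    """Settings for one full consistency evaluation of one dataset."""

    preset: str | None = "moral"
    data_dir: str | Path | None = None
    acf_params: ACFParams | None = None
    noise: NoiseInjectionConfig = field(default_factory=NoiseInjectionConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    n_repetitions: int = 10
    master_seed: int = 0
    out_dir: str | Path | None = None
    reuse_mc_thresholds: bool = True

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.preset is None and self.data_dir is None:
            raise ValueError("either preset or data_dir must be given")
        if self.preset is not None and self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


@dataclass
class AnovaResult:
    metric: str
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    letters: dict[str, str]


def _load_dataset(cfg: EvaluationConfig) -> SubjectDataset:
    if cfg.data_dir is not None:
        d = Path(cfg.data_dir)
        paths = sorted(d.glob("subject_*.nii*"))
        if len(paths) < 2:
            raise ValueError(f"no subject volumes found under {d}")
        images = [image_io.read_volume(p) for p in paths]
        mask_path = d / "mask.nii.gz"
        if mask_path.exists():
            mask = image_io.read_mask(mask_path)
        else:
            mask = image_io.intersect_mask(images, "all_finite")
        return SubjectDataset(images, mask)
    sim = _PRESETS[cfg.preset](derive_seed(cfg.master_seed, 1000))
    return simulate_dataset(sim)


def _run_five(
    dataset: SubjectDataset,
    tcfg: ThresholdConfig,
    mc_cache: dict | None,
) -> dict[str, ThresholdResult]:
    """Run all five conditions with per-method seed streams.

    ``mc_cache`` (method name -> (noise_model, k_star)) lets the two
    Monte-Carlo conditions reuse a calibration computed on the same mask.
    """
    out: dict[str, ThresholdResult] = {}
    for idx, name in enumerate(METHOD_NAMES):
        mcfg = replace(tcfg, seed=derive_seed(tcfg.seed, idx))
        if name == "snpm_voxel":
            out[name] = snpm_voxelwise(dataset, mcfg)
        elif name == "snpm_cluster":
            out[name] = snpm_clusterwise(dataset, mcfg)
        elif name in ("clustsim", "clustsim_acf"):
            use_acf = name == "clustsim_acf"
            cached = mc_cache.get(name) if mc_cache is not None else None
            if cached is None:
                res = clustsim_threshold(dataset, mcfg, use_acf=use_acf)
                if mc_cache is not None:
                    model = res.thresholds.get("acf")
                    noise_model = (
                        ACFParams(*model)
                        if model is not None
                        else {"fwhm_mm": res.thresholds["fwhm_mm"]}
                    )
                    mc_cache[name] = (noise_model, res.thresholds["k_star"])
            else:
                noise_model, k_star = cached
                res = clustsim_threshold(
                    dataset, mcfg, use_acf=use_acf,
                    noise_model=noise_model, k_star=k_star,
                )
            out[name] = res
        elif name == "tfce":
            out[name] = tfce_fwe(dataset, mcfg)
    return out


def run_evaluation(cfg: EvaluationConfig) -> pd.DataFrame:
    """Execute the full design; returns the table of consistency records.

    Columns: method, repetition, false_alarm, hit (NaN where a rate is
    undefined).  Fully reproducible from ``cfg.master_seed``.  When
    ``cfg.out_dir`` is set, also writes the records, the ANOVA results, the
    binary maps and a run manifest there.
    """
    dataset = _load_dataset(cfg)
    acf_params = cfg.acf_params
    if acf_params is None:
        acf_params = dataset_residual_acf(dataset, cfg.threshold.acf_r_max_mm)
        logger.info(
            "fitted noise ACF from residuals: a=%.3f b=%.2f c=%.2f",
            acf_params.a, acf_params.b, acf_params.c,
        )
    tcfg = replace(cfg.threshold, seed=derive_seed(cfg.master_seed, 2000))
    mc_cache: dict | None = {} if cfg.reuse_mc_thresholds else None

    reference = _run_five(dataset, tcfg, mc_cache)

    rows = []
    noisy_results: dict[int, dict[str, ThresholdResult]] = {}
    for rep in range(1, cfg.n_repetitions + 1):
        noise_cfg = replace(cfg.noise, seed=derive_seed(cfg.master_seed, 3000, rep))
        noisy = inject_noise(dataset, acf_params, noise_cfg)
        # identical tcfg.seed: per-method permutation streams repeat exactly
        results = _run_five(noisy, tcfg, mc_cache)
        noisy_results[rep] = results
        for name in METHOD_NAMES:
            fa = false_alarm_rate(reference[name].survivors, results[name].survivors)
            ht = hit_rate(reference[name].survivors, results[name].survivors)
            if fa is None or ht is None:
                logger.warning(
                    "undefined rate for method=%s repetition=%d", name, rep
                )
            rows.append(
                {
                    "method": name,
                    "repetition": rep,
                    "false_alarm": np.nan if fa is None else fa,
                    "hit": np.nan if ht is None else ht,
                }
            )
    records = pd.DataFrame(rows)
    records.attrs["n_survivors_original"] = {
        name: reference[name].n_survivors for name in METHOD_NAMES
    }
    records.attrs["acf_params"] = (acf_params.a, acf_params.b, acf_params.c)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            anovas = [
                anova_consistency(records, metric) for metric in ("false_alarm", "hit")
            ]
        except ValueError as exc:
            logger.warning("ANOVA skipped: %s", exc)
            anovas = []
        report(records, anovas, out)
        grid = dataset.grid
        for name, res in reference.items():
            write_volume(
                ContrastImage(grid, res.survivors.astype(np.float64)),
                out / f"survivors_original_{name}.nii.gz",
            )
        manifest = {
            "master_seed": cfg.master_seed,
            "preset": cfg.preset,
            "n_repetitions": cfg.n_repetitions,
            "acf_params": dataclasses.asdict(acf_params),
            "threshold_config": dataclasses.asdict(tcfg),
            "noise_config": dataclasses.asdict(cfg.noise),
            "n_survivors_original": {
                name: reference[name].n_survivors for name in METHOD_NAMES
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records


# ---------------------------------------------------------------------------
# One-way ANOVA and Scheffe post-hoc grouping
# ---------------------------------------------------------------------------


def _groups(records: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    if metric not in ("false_alarm", "hit"):
        raise ValueError(f"unknown metric {metric!r}")
    groups = {}
    for name, sub in records.groupby("method", sort=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if len(vals) >= 2:
            groups[name] = vals
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 methods with >= 2 defined observations for {metric}"
        )
    return groups


def _anova_ss(groups: dict[str, np.ndarray]):
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return ss_between, ss_within, df_between, df_within


def anova_consistency(records: pd.DataFrame, metric: str) -> AnovaResult:
    """One-way fixed-effects ANOVA of a rate across methods.

    F = MS_between / MS_within with the textbook sums of squares; F is
    defined as 0 when both mean squares vanish (all observations
    identical).  Undefined (NaN) rates are excluded.
    """
    groups = _groups(records, metric)
    ss_b, ss_w, df_b, df_w = _anova_ss(groups)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w if df_w > 0 else 0.0
    # guard numerically-zero mean squares (all observations identical)
    grand = float(np.concatenate(list(groups.values())).mean())
    tol = 1e-12 * max(1.0, grand * grand)
    if ms_w <= tol:
        F = 0.0 if ms_b <= tol else float("inf")
    else:
        F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    means = {name: float(g.mean()) for name, g in groups.items()}
    letters = scheffe_posthoc(records, metric)
    return AnovaResult(
        metric=metric,
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means=means,
        letters=letters,
    )


def scheffe_pairwise_significant(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[tuple[str, str], bool]:
    """Scheffe criterion for every method pair.

    The pair (i, j) differs significantly when
    (mean_i - mean_j)^2 / (MS_within * (1/n_i + 1/n_j)) exceeds
    (k - 1) * F_crit(k - 1, df_within, alpha).
    """
    ss_b, ss_w, df_b, df_w = _anova_ss(groups)
    ms_w = ss_w / df_w if df_w > 0 else 0.0
    k = len(groups)
    f_crit = float(stats.f.isf(alpha, k - 1, df_w))
    grand = float(np.concatenate(list(groups.values())).mean())
    tol = 1e-12 * max(1.0, grand * grand)
    out = {}
    names = list(groups)
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            gi, gj = groups[ni], groups[nj]
            diff2 = (gi.mean() - gj.mean()) ** 2
            denom = ms_w * (1.0 / len(gi) + 1.0 / len(gj))
            if denom <= tol:
                sig = diff2 > tol
            else:
                sig = diff2 / denom > (k - 1) * f_crit
            out[(ni, nj)] = bool(sig)
            out[(nj, ni)] = bool(sig)
    return out


def scheffe_posthoc(
    records: pd.DataFrame, metric: str, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from Scheffe pairwise tests.

    Methods are sorted by group mean; every maximal run of consecutive
    methods that are mutually non-significant shares one letter, and each
    method's label is the concatenation of the letters of the runs it
    belongs to.
    """
    groups = _groups(records, metric)
    sig = scheffe_pairwise_significant(groups, alpha)
    names = sorted(groups, key=lambda n: groups[n].mean())
    runs = []
    start = 0
    while start < len(names):
        end = start
        while end + 1 < len(names) and all(
            not sig[(names[a], names[end + 1])] for a in range(start, end + 1)
        ):
            end += 1
        runs.append((start, end))
        start += 1
    # keep only maximal runs
    maximal = [
        (s, e)
        for s, e in runs
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in runs)
    ]
    maximal.sort()
    letters = {n: "" for n in names}
    for li, (s, e) in enumerate(maximal):
        letter = chr(ord("a") + li % 26)
        for n in names[s : e + 1]:
            letters[n] += letter
    return letters


def report(records: pd.DataFrame, anovas: list[AnovaResult], out_dir: str | Path):
    """Write records.csv, anova.json and per-metric violin plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    payload = {
        a.metric: {
            "F": a.F,
            "df_between": a.df_between,
            "df_within": a.df_within,
            "p": a.p,
            "group_means": a.group_means,
            "letters": a.letters,
        }
        for a in anovas
    }
    (out / "anova.json").write_text(json.dumps(payload, indent=2))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for a in anovas:
        fig, ax = plt.subplots(figsize=(6, 4))
        data, labels = [], []
        for name in METHOD_NAMES:
            vals = records.loc[records["method"] == name, a.metric].dropna()
            if len(vals):
                data.append(vals.to_numpy())
                labels.append(name)
        if data:
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(labels) + 1))
            ax.set_xticklabels(labels, rotation=30, ha="right")
            for i, name in enumerate(labels, start=1):
                ax.annotate(
                    a.letters.get(name, ""),
                    (i, max(data[i - 1]) if len(data[i - 1]) else 0),
                    ha="center", va="bottom", fontsize=10,
                )
        ax.set_ylabel(a.metric.replace("_", " "))
        ax.set_title(
            f"{a.metric}: F({a.df_between}, {a.df_within}) = {a.F:.2f}, p = {a.p:.2g}"
        )
        fig.tight_layout()
        fig.savefig(out / f"{a.metric}.png", dpi=100)
        plt.close(fig)
    return out
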