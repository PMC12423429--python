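"""Study-level orchestration: volumes, reliability, agreement, summary.

Stages (all long-format pandas in, tidy tables out):

1. :func:`build_volume_records` — turn every CSA series into truncated-cone
   (US and MRI) and Cavalieri (MRI only) volumes and every fascia image
   pair into a trial thickness.
2. :func:`reliability_table` — per (group, structure, modality, method):
   ICC(3,1), SEm, MDD and relative MDD% from the trial-1/trial-2 matrix.
3. :func:`comparison_table` — Pearson r and Bland–Altman bias/LoA/LoA% for
   the four standard method pairs (differences are first-minus-second).
4. :func:`summary_table` — group means ± SD and the PF vs non-PF Welch test.

Feet are treated as independent observations throughout (both feet of a
participant may appear, one per group); no clustering correction is made.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io as fio
from .agreement import BlandAltman, ReliabilityAnalysis, welch_t
from .morphometry import cavalieri_volume, thickness_from_pair, truncated_cone_volume
from .simulate import StudyConfig, StudyDataset, simulate_study

__all__ = [
    "METHOD_PAIRS",
    "build_volume_records",
    "reliability_table",
    "comparison_table",
    "summary_table",
    "run_study",
]

logger = logging.getLogger(__name__)

FOOT_KEY = ["participant_id", "foot", "group"]

#: the four standard method pairs (first minus second), per group
METHOD_PAIRS = (
    ("US-MRI plantar fascia", ("fascia", "US", "thickness"), ("fascia", "MRI", "thickness")),
    ("FDB MRI truncated cone-MRI Cavalieri", ("FDB", "MRI", "truncated_cone"), ("FDB", "MRI", "cavalieri")),
    ("FDB US truncated cone-MRI Cavalieri", ("FDB", "US", "truncated_cone"), ("FDB", "MRI", "cavalieri")),
    ("FDB US truncated cone-MRI truncated cone", ("FDB", "US", "truncated_cone"), ("FDB", "MRI", "truncated_cone")),
)


def build_volume_records(dataset: StudyDataset, end_caps: bool = False) -> StudyDataset:
    """Attach the per-trial scalar value table to a study dataset.

    FDB series gain a truncated-cone volume (both modalities) and, for
    MRI, a Cavalieri volume; fascia image pairs are averaged into a trial
    thickness.  Every (foot, structure, modality, method) must carry
    exactly two trials; a missing trial raises a ``ValueError`` naming the
    offending key.
    """
    spacing = dataset.config.slice_spacing if dataset.config else 0.5
    rows = []
    if len(dataset.slices):
        series = fio.series_from_slices(dataset.slices, spacing=spacing)
        for (pid, foot, group, modality, trial), s in series.items():
            tc = truncated_cone_volume(s, end_caps=end_caps)
            rows.append((pid, foot, group, "FDB", modality, "truncated_cone", trial, tc.value))
            if modality == "MRI":
                cav = cavalieri_volume(s)
                rows.append((pid, foot, group, "FDB", modality, "cavalieri", trial, cav.value))
    for rec in dataset.thickness.itertuples(index=False):
        value = thickness_from_pair(rec.image_1_mm, rec.image_2_mm)
        rows.append(
            (rec.participant_id, rec.foot, rec.group, "fascia", rec.modality, "thickness", rec.trial, value)
        )
    values = pd.DataFrame(
        rows,
        columns=FOOT_KEY + ["structure", "modality", "method", "trial", "value"],
    ).sort_values(FOOT_KEY + ["structure", "modality", "method", "trial"]).reset_index(drop=True)

    counts = values.groupby(FOOT_KEY + ["structure", "modality", "method"])["trial"].nunique()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(f"expected exactly 2 trials per measurement; offending keys: {bad.index.tolist()[:5]}")
    return StudyDataset(
        slices=dataset.slices, thickness=dataset.thickness, values=values, config=dataset.config
    )


def _require_values(dataset: StudyDataset) -> pd.DataFrame:
    if dataset.values is None:
        raise ValueError("run build_volume_records first")
    return dataset.values


def _trial_matrix(sub: pd.DataFrame) -> np.ndarray:
    wide = sub.pivot_table(index=["participant_id", "foot"], columns="trial", values="value")
    return wide.to_numpy()


def reliability_table(dataset: StudyDataset, sd_mode: str = "pooled") -> pd.DataFrame:
    """Per-key test-retest reliability: the study's Table-1 analog.

    One row per (group, structure, modality, method) present in the data,
    using the two trials of every foot as the repeated measures.
    """
    values = _require_values(dataset)
    rows = []
    for (group, structure, modality, method), sub in values.groupby(
        ["group", "structure", "modality", "method"], sort=True
    ):
        mat = _trial_matrix(sub)
        if mat.shape[0] < 3:
            raise ValueError(
                f"group {group!r} has only {mat.shape[0]} feet for "
                f"({structure}, {modality}, {method}); need >= 3"
            )
        rel = ReliabilityAnalysis(sd_mode=sd_mode).fit(mat)
        rows.append(
            {
                "group": group,
                "structure": structure,
                "modality": modality,
                "method": method,
                "n_feet": rel.n_,
                "mean": rel.mean_,
                "sd": rel.sd_,
                "icc": rel.icc_.estimate,
                "icc_ci_low": rel.icc_.ci_low,
                "icc_ci_high": rel.icc_.ci_high,
                "sem": rel.sem_,
                "sem_ci_low": rel.sem_ci_[0],
                "sem_ci_high": rel.sem_ci_[1],
                "mdd": rel.mdd_,
                "mdd_pct": rel.mdd_pct_,
            }
        )
    return pd.DataFrame(rows)


def _foot_values(values: pd.DataFrame, key, trial_handling: str) -> pd.Series:
    structure, modality, method = key
    sub = values[
        (values["structure"] == structure)
        & (values["modality"] == modality)
        & (values["method"] == method)
    ]
    if trial_handling == "mean":
        return sub.groupby(["participant_id", "foot"])["value"].mean()
    if trial_handling == "trial_1":
        return sub[sub["trial"] == 1].set_index(["participant_id", "foot"])["value"]
    raise ValueError(f"unknown trial_handling {trial_handling!r}")


def comparison_table(dataset: StudyDataset, trial_handling: str = "mean"):
    """Method-pair agreement per group: the study's Table-2 analog.

    Per-foot values entering a pair are the mean of the two trials by
    default (``trial_handling="trial_1"`` uses the first trial only).
    Returns ``(table, points)`` where ``points`` holds the per-foot
    (mean, difference) pairs for Bland–Altman plotting.
    """
    values = _require_values(dataset)
    rows, points = [], []
    for group in sorted(values["group"].unique()):
        gvals = values[values["group"] == group]
        for label, key_a, key_b in METHOD_PAIRS:
            a = _foot_values(gvals, key_a, trial_handling)
            b = _foot_values(gvals, key_b, trial_handling)
            joined = pd.concat([a.rename("a"), b.rename("b")], axis=1).dropna()
            if len(joined) < 3:
                raise ValueError(f"pair {label!r} in group {group!r} has < 3 feet")
            ba = BlandAltman().fit(joined["a"], joined["b"])
            cmp_ = ba.comparison_()
            rows.append(
                {
                    "group": group,
                    "pair": label,
                    "n_feet": cmp_.n,
                    "r": cmp_.r,
                    "r_squared": cmp_.r**2,
                    "bias": cmp_.bias,
                    "loa_low": cmp_.loa_low,
                    "loa_high": cmp_.loa_high,
                    "loa_pct": cmp_.loa_pct,
                    "reference_mean": cmp_.reference_mean,
                }
            )
            for (pid, foot), m, d in zip(joined.index, cmp_.means, cmp_.diffs):
                points.append(
                    {"group": group, "pair": label, "participant_id": pid, "foot": foot, "mean": m, "difference": d}
                )
    return pd.DataFrame(rows), pd.DataFrame(points)


def summary_table(dataset: StudyDataset, trial_handling: str = "mean"):
    """Group means ± SD and PF vs non-PF Welch tests: the Table-3 analog.

    Returns ``(summary, tests)``; means are over per-foot trial means.
    """
    values = _require_values(dataset)
    per_foot = (
        values.groupby(["group", "structure", "modality", "method", "participant_id", "foot"])["value"]
        .mean()
        .reset_index()
        if trial_handling == "mean"
        else values[values["trial"] == 1]
    )
    summary = (
        per_foot.groupby(["structure", "modality", "method", "group"])["value"]
        .agg(n_feet="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    tests = []
    for (structure, modality, method), sub in per_foot.groupby(["structure", "modality", "method"]):
        by_group = {g: s["value"].to_numpy() for g, s in sub.groupby("group")}
        if len(by_group) != 2:
            continue
        pf, non = by_group.get("PF"), by_group.get("non-PF")
        if pf is None or non is None or len(pf) < 2 or len(non) < 2:
            continue
        stat, p = welch_t(pf, non)
        tests.append(
            {
                "structure": structure,
                "modality": modality,
                "method": method,
                "t_statistic": stat,
                "p_value": p,
                "mean_diff_pf_minus_nonpf": float(pf.mean() - non.mean()),
            }
        )
    return summary, pd.DataFrame(tests)


def run_study(
    config: StudyConfig | None = None,
    config_path=None,
    outdir=None,
    seed: int | None = None,
    simulate: bool = True,
    slices_path=None,
    thickness_path=None,
    trial_handling: str = "mean",
    sd_mode: str = "pooled",
    end_caps: bool = False,
) -> dict:
    """End-to-end run: data in (simulated or CSV), all report tables out.

    Returns the bundle of tables; if ``outdir`` is given, also writes them
    as CSV plus a JSON run manifest.  Deterministic for fixed seed/config.
    """
    if config is None:
        config = fio.load_config(config_path)
    if simulate:
        dataset = simulate_study(config, seed=seed)
    else:
        slices = fio.read_csa_csv(slices_path, spacing=config.slice_spacing) if slices_path else pd.DataFrame(columns=fio.SLICE_COLUMNS)
        thickness = fio.read_thickness_csv(thickness_path) if thickness_path else pd.DataFrame(columns=fio.THICKNESS_COLUMNS)
        dataset = StudyDataset(slices=slices, thickness=thickness, config=config)
    dataset = build_volume_records(dataset, end_caps=end_caps)
    reliability = reliability_table(dataset, sd_mode=sd_mode)
    comparison, points = comparison_table(dataset, trial_handling=trial_handling)
    summary, tests = summary_table(dataset, trial_handling=trial_handling)
    bundle = {
        "reliability": reliability,
        "comparison": comparison,
        "bland_altman_points": points,
        "summary": summary,
        "group_tests": tests,
        "values": dataset.values,
    }
    if outdir is not None:
        fio.write_tables(bundle, outdir, config=config, seed=seed if seed is not None else config.seed)
    logger.info(
        "study run complete: %d reliability rows, %d comparisons, %d summary rows",
        len(reliability),
        len(comparison),
        len(summary),
    )
    return bundle
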