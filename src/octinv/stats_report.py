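"""Group comparisons over metric tables, and the end-to-end pipeline.

The comparison design mirrors the study layout: a 2x2x2 crossing of cancer
cell line, stromal cell type and culture day.  Cell-line and stroma factors
are compared with Welch's unequal-variance t-test, the day factor with the
Mann-Whitney U test (exact distribution for small tie-free samples, normal
approximation with tie correction otherwise), both two-sided at alpha 0.05
per comparison with no multiplicity correction (the report states the number
of comparisons so users can apply their own).  Day comparisons ignore the
pairing of re-imaged models deliberately.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

import octinv
from octinv.metrics import compute_metrics_3d
from octinv.partition import estimate_baseline, partition_cancer
from octinv.phantom import PhantomSpec, build_label_volume, render_oct, extract_slice
from octinv.segmentation import FeatureSpec, clean_mask, segment_volume, train_classifier
from octinv.volume_io import METRIC_COLUMNS, write_metrics

logger = logging.getLogger(__name__)

ALPHA = 0.05
FACTORS = ("cell_line", "stroma", "day")


@dataclass
class ComparisonResult:
    comparison: str
    test: str
    statistic: float
    p_value: float
    significant: bool
    n1: int
    n2: int


def _check_groups(a: np.ndarray, b: np.ndarray) -> None:
    for name, g in (("first", a), ("second", b)):
        if g.size < 2:
            raise ValueError(f"{name} group has n={g.size} < 2")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"{name} group contains non-finite values")


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test: (statistic, p) via Welch-Satterthwaite df.

    Degenerate convention: when both groups have zero variance, p = 1 for
    equal means (logged) and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_groups(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("welch_ttest: both groups constant and equal; p = 1 by convention")
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def mann_whitney_u(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for tie-free samples with both
    n <= ``exact_max_n``, otherwise normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_groups(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties and np.unique(pooled).size == 1:
        logger.warning("mann_whitney_u: all values tied; p = 1 by convention")
        return float(a.size * b.size) / 2.0, 1.0
    method = "exact" if (not has_ties and max(a.size, b.size) <= exact_max_n) else "asymptotic"
    if has_ties:
        logger.info("mann_whitney_u: ties present, using tie-corrected normal approximation")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _result(label: str, test: str, stat: float, p: float, n1: int, n2: int) -> ComparisonResult:
    return ComparisonResult(comparison=label, test=test, statistic=stat, p_value=p,
                            significant=bool(p < ALPHA), n1=n1, n2=n2)


def compare_factor(table: pd.DataFrame, factor: str, metric: str) -> list[ComparisonResult]:
    """Welch comparisons of ``metric`` between the two levels of ``factor``
    (cell_line or stroma), one per combination of the other design factors."""
    if factor not in ("cell_line", "stroma"):
        raise ValueError("factor must be 'cell_line' or 'stroma'")
    levels = sorted(table[factor].unique())
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {levels}")
    others = [f for f in FACTORS if f != factor]
    results = []
    for keys, sub in table.groupby(others, sort=True):
        g1 = sub.loc[sub[factor] == levels[0], metric].to_numpy(dtype=float)
        g2 = sub.loc[sub[factor] == levels[1], metric].to_numpy(dtype=float)
        cond = ", ".join(f"{k}={v}" for k, v in zip(others, keys))
        t, p = welch_ttest(g1, g2)
        results.append(_result(f"{factor} {levels[0]} vs {levels[1]} | {cond}",
                               "welch_t", t, p, g1.size, g2.size))
    return results


def compare_days(table: pd.DataFrame, metric: str) -> list[ComparisonResult]:
    """Mann-Whitney comparisons of ``metric`` between the two days, one per
    (cell_line, stroma) condition."""
    days = sorted(table["day"].unique())
    if len(days) != 2:
        raise ValueError(f"day factor must have exactly 2 levels, got {days}")
    results = []
    for (cl, st), sub in table.groupby(["cell_line", "stroma"], sort=True):
        g1 = sub.loc[sub["day"] == days[0], metric].to_numpy(dtype=float)
        g2 = sub.loc[sub["day"] == days[1], metric].to_numpy(dtype=float)
        u, p = mann_whitney_u(g1, g2)
        results.append(_result(f"day {days[0]} vs {days[1]} | cell_line={cl}, stroma={st}",
                               "mann_whitney_u", u, p, g1.size, g2.size))
    return results


def comparisons_frame(results: list[ComparisonResult], metric: str) -> pd.DataFrame:
    rows = [{"metric": metric, **asdict(r)} for r in results]
    return pd.DataFrame(rows, columns=["metric", "comparison", "test", "statistic",
                                       "p_value", "significant", "n1", "n2"])


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0])


def _merge_spec(base: dict, overrides: dict | None) -> PhantomSpec:
    d = dict(base)
    d.update(overrides or {})
    return PhantomSpec.from_dict(d)


def _check_design(conditions: list[dict]) -> None:
    levels = {f: sorted({c[f] for c in conditions}) for f in FACTORS}
    present = {(c["cell_line"], c["stroma"], c["day"]) for c in conditions}
    missing = [(cl, st, d)
               for cl in levels["cell_line"] for st in levels["stroma"] for d in levels["day"]
               if (cl, st, d) not in present]
    if missing:
        raise ValueError("design is not a full crossing; missing condition cells: "
                         + ", ".join(f"(cell_line={cl}, stroma={st}, day={d})" for cl, st, d in missing))


def _train_from_config(base: dict, training: dict, seed: int):
    patterns = training.get("patterns", ["cohesive", "finger", "island"])
    n_slices = int(training.get("n_slices", 24))
    per = max(1, n_slices // len(patterns))
    slices = []
    for pi, pattern in enumerate(patterns):
        spec = _merge_spec(base, {"invasion_pattern": pattern})
        s = _child_seed(seed, 1000, pi)
        truth = build_label_volume(spec, seed=s)
        vol = render_oct(truth, spec, seed=s)
        ny = vol.shape[1]
        for y in np.linspace(0, ny - 1, per).astype(int):
            slices.append((extract_slice(vol, "XZ", int(y)),
                           extract_slice(truth.label_volume, "XZ", int(y))))
    fs = FeatureSpec(**training.get("feature_spec", {}))
    return train_classifier(slices, fs, voxel_um=float(base.get("voxel_um", 1.0)),
                            seed=_child_seed(seed, 1001))


def run_pipeline(config: dict | str | os.PathLike, out_dir: str | os.PathLike | None = None) -> dict:
    """Run phantom -> segment -> partition -> quantify -> compare.

    ``config`` is a dict or a YAML path with keys ``seed``, ``base_phantom``,
    ``conditions`` (list of cells with cell_line/stroma/day/n_replicates and
    optional per-condition ``phantom`` overrides), optional ``training``,
    ``segmentation`` ('classifier' or 'truth'), ``mass_index_form`` and
    ``metrics``.  Deterministic given the config.  Returns a report dict with
    the metrics table, the comparisons table and a provenance log; writes
    ``metrics.csv``, ``comparisons.csv`` and ``log.json`` under ``out_dir``
    when given.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    base = dict(config.get("base_phantom", {}))
    conditions = config["conditions"]
    if not conditions:
        raise ValueError("config.conditions is empty")
    _check_design(conditions)
    seg_mode = config.get("segmentation", "classifier")
    if seg_mode not in ("classifier", "truth"):
        raise ValueError(f"segmentation must be 'classifier' or 'truth', got {seg_mode!r}")
    mass_form = config.get("mass_index_form", "invasive_fraction")
    metric_names = config.get("metrics", ["v_iccr_um3"])

    classifier = None
    if seg_mode == "classifier":
        try:
            classifier = _train_from_config(base, dict(config.get("training", {})), seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'training' failed: {exc}") from exc

    rows = []
    for ci, cond in enumerate(conditions):
        spec = _merge_spec(base, cond.get("phantom"))
        for r in range(int(cond.get("n_replicates", 3))):
            s = _child_seed(seed, ci, r)
            try:
                truth = build_label_volume(spec, seed=s)
                vol = render_oct(truth, spec, seed=s)
                if classifier is not None:
                    labels = segment_volume(vol, classifier)
                else:
                    labels = truth.label_volume
                cancer = clean_mask(labels.cancer_mask(), voxel_um=labels.voxel_um)
                baseline = estimate_baseline(cancer, labels.voxel_um)
                part = partition_cancer(cancer, baseline, labels.voxel_um)
                m = compute_metrics_3d(part, mass_index_form=mass_form)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'quantify' failed for condition "
                    f"(cell_line={cond['cell_line']}, stroma={cond['stroma']}, "
                    f"day={cond['day']}) replicate {r}: {exc}") from exc
            rows.append({
                "model_id": f"{cond['cell_line']}-{cond['stroma']}-d{cond['day']}-r{r}",
                "cell_line": cond["cell_line"], "stroma": cond["stroma"],
                "day": cond["day"], "replicate": r,
                "v_total_um3": m.v_total_um3, "v_original_um3": m.v_original_um3,
                "v_iccr_um3": m.v_iccr_um3, "hif_area_um2": m.hif_area_um2,
                "mass_invasion_index": m.mass_invasion_index,
                "depth_of_invasion_um": m.depth_of_invasion_um,
            })
    metrics_table = pd.DataFrame(rows, columns=METRIC_COLUMNS)

    comp_frames = []
    for metric in metric_names:
        results = (compare_factor(metrics_table, "cell_line", metric)
                   + compare_factor(metrics_table, "stroma", metric)
                   + compare_days(metrics_table, metric))
        comp_frames.append(comparisons_frame(results, metric))
    comparisons = pd.concat(comp_frames, ignore_index=True)

    log = {
        "seed": seed,
        "octinv_version": octinv.__version__,
        "numpy_version": np.__version__,
        "segmentation": seg_mode,
        "mass_index_form": mass_form,
        "n_comparisons": int(len(comparisons)),
        "alpha": ALPHA,
        "note": "day comparisons treat re-imaged models as independent samples (pairing ignored)",
    }
    report = {"metrics": metrics_table, "comparisons": comparisons, "log": log}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_metrics(metrics_table, os.path.join(out_dir, "metrics.csv"))
        comparisons.to_csv(os.path.join(out_dir, "comparisons.csv"), index=False)
        with open(os.path.join(out_dir, "log.json"), "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2)
    return report
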