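"""Canned study-level analyses on synthetic cohorts.

One call runs the full chain for one master seed at the default study
conditions (balanced GH/SI cohort of 18 subjects per group, 3-minute
baseline + 10-minute test at 30 fps, default generator contrast): scoring,
composite aversion statistics, behavior-feature decoding, and optionally the
unsupervised map with occupancy decoding.  These are the entry points used
for reproducing the headline numbers (mean decoder training accuracies)
and for calibration checks on null cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aversion import HousingDecoder, composite_aversion, group_ttest
from .behavior_map import map_cohort, region_stats_and_decode
from .ethogram import score_cohort
from .synthetic import ConditionParams, GeneratorConfig, simulate_cohort


@dataclass
class CohortResult:
    """Per-seed summary of the standard analysis chain."""

    seed: int
    n_per_group: int
    conditions: tuple[str, str]
    score_table: pd.DataFrame
    composite_by_group: dict[str, float]
    effect_size: float            # standardized (pooled-sd) composite difference
    t: float
    p: float
    feature_accuracy: float       # behavior-score decoder, training accuracy
    occupancy_accuracy: float | None = None
    n_regions: int | None = None
    top_region: str | None = None


def decoder_features(score_table: pd.DataFrame) -> pd.DataFrame:
    """Numeric behavior-score features with flagged-missing entries
    mean-imputed (neutral on the decoder's standardized scale)."""
    feats = score_table.drop(
        columns=[c for c in ("condition", "sex") if c in score_table.columns]
    ).astype(float)
    return feats.fillna(feats.mean())


def run_cohort(
    seed: int,
    config: GeneratorConfig | None = None,
    n_per_group: int = 18,
    conditions: tuple[str, str] = ("GH", "SI"),
    with_map: bool = True,
    stride: int = 60,
    l2_strength: float = 1.0,
) -> CohortResult:
    """Simulate, score, and decode one cohort under one master seed."""
    config = config or GeneratorConfig()
    cohort = simulate_cohort(config, n_per_group, conditions, seed)
    recs = [r for r, _ in cohort]
    table = score_cohort(recs, config.session_config())
    labels = table["condition"].to_numpy()

    # constant behaviors (e.g. a cohort in which nobody ever reversed) carry
    # no group information; drop them rather than fail the whole analysis
    comp = composite_aversion(table, on_degenerate="drop")["composite"]
    a = comp[labels == conditions[0]]
    b = comp[labels == conditions[1]]
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    tt = group_ttest(comp.to_numpy(), labels)

    dec = HousingDecoder(l2_strength=l2_strength)
    dec.fit(decoder_features(table), labels)

    result = CohortResult(
        seed=seed,
        n_per_group=n_per_group,
        conditions=conditions,
        score_table=table,
        composite_by_group={
            conditions[0]: float(a.mean()), conditions[1]: float(b.mean())
        },
        effect_size=float((b.mean() - a.mean()) / pooled) if pooled > 0 else np.inf,
        t=tt.t,
        p=tt.p,
        feature_accuracy=dec.training_accuracy_,
    )
    if with_map:
        cm = map_cohort(recs, stride=stride, seed=seed)
        _, report = region_stats_and_decode(
            cm.occupancy, cm.subject_labels.to_numpy(), cm.excluded_regions,
            l2_strength=l2_strength,
        )
        result.occupancy_accuracy = report.training_accuracy
        result.n_regions = cm.map.n_regions
        result.top_region = str(report.ranked_features().index[0])
    return result


def null_config() -> GeneratorConfig:
    """Both groups share the GH parameters (no true difference)."""
    gh = ConditionParams()
    return GeneratorConfig(conditions={"GH": gh, "SI": gh})


def run_null_cohort(seed: int, n_per_group: int = 18, **kwargs) -> CohortResult:
    return run_cohort(
        seed, config=null_config(), n_per_group=n_per_group,
        with_map=False, **kwargs,
    )
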