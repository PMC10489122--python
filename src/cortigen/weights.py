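"""SVM weight-map summarisation.

The coefficients of a linear SVM's separating hyperplane quantify how
much each (normalised) feature contributes to the discrimination.  Two
summaries make the map interpretable anatomically:

* region importance — for each region, the sum of the absolute
  coefficients over that region's metrics (4 for cortical parcels, 1
  for subcortical volumes);
* per-metric direction — for each metric, the sum of the positive
  coefficients and the sum of the negative coefficients across regions,
  kept separate so that a metric pushing carriers both ways is visible.

Fold-wise hyperplanes are first averaged in full feature space (zeros
for features a fold's screen discarded), then summarised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import parse_feature_name, region_of_feature


@dataclass
class WeightMap:
    """Summarised discriminative map of a linear SVM ensemble."""

    feature_weights: pd.Series  # signed, full feature space
    region_importance: pd.Series  # sum of |w| over each region's metrics
    metric_positive_sum: pd.Series  # per metric, sum of positive weights
    metric_negative_sum: pd.Series  # per metric, sum of negative weights

    def top_regions(self, n: int = 6) -> pd.Series:
        return self.region_importance.sort_values(ascending=False).head(n)

    def to_frame(self) -> pd.DataFrame:
        """Long table (feature, weight, region, metric) for TSV export."""
        rows = []
        for name, w in self.feature_weights.items():
            hemi, region, metric = parse_feature_name(name)
            rows.append({"feature": name, "weight": w, "region": f"{hemi}_{region}", "metric": metric})
        return pd.DataFrame(rows)


def summarize_weights(fold_weights, feature_names=None) -> WeightMap:
    """Average fold-wise hyperplanes and summarise by region and metric.

    ``fold_weights`` may be a DataFrame (folds x features), a list of
    Series, or a list of arrays with ``feature_names`` given.  All
    feature names must be canonical ``<hemi>_<region>_<metric>`` — an
    unknown name raises.
    """
    if isinstance(fold_weights, pd.DataFrame):
        W = fold_weights
    elif len(fold_weights) and isinstance(fold_weights[0], pd.Series):
        W = pd.DataFrame([s for s in fold_weights])
    else:
        if feature_names is None:
            raise ValueError("feature_names required when fold weights are plain arrays")
        W = pd.DataFrame(np.asarray(fold_weights, dtype=float), columns=list(feature_names))

    mean_w = W.mean(axis=0)
    regions = [region_of_feature(n) for n in mean_w.index]  # validates names
    metrics = [parse_feature_name(n)[2] for n in mean_w.index]

    frame = pd.DataFrame({"w": mean_w.to_numpy(), "region": regions, "metric": metrics}, index=mean_w.index)
    region_importance = frame.assign(a=frame["w"].abs()).groupby("region", sort=True)["a"].sum()
    pos = frame.assign(p=frame["w"].clip(lower=0)).groupby("metric", sort=True)["p"].sum()
    neg = frame.assign(m=frame["w"].clip(upper=0)).groupby("metric", sort=True)["m"].sum()

    return WeightMap(
        feature_weights=mean_w,
        region_importance=region_importance,
        metric_positive_sum=pos,
        metric_negative_sum=neg,
    )
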