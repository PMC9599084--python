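"""Hierarchical clustering of DE features for heatmap-ready output.

Samples (and features) are clustered by average linkage on the
1 - Pearson-correlation distance of z-scored normalized expression —
the common heatmap default.  The output is everything a heatmap needs:
the reordered z-score matrix, both linkage trees with their merge
heights, and summary counts of declared up-/down-regulated features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["cluster_and_report"]


def _corr_dist_linkage(mat: np.ndarray) -> np.ndarray:
    """Average-linkage tree on 1 - Pearson distance between rows."""
    # constant rows have undefined correlation; treat them as maximally
    # uninformative (distance 1 to everything)
    d = pdist(mat, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    d = np.clip(d, 0.0, None)
    return hierarchy.linkage(d, method="average")


def cluster_and_report(
    matrix: pd.DataFrame,
    groups: pd.Series | None = None,
    up: set | None = None,
    down: set | None = None,
    feature_classes: pd.Series | None = None,
) -> dict:
    """Cluster a normalized DE-feature matrix and summarize it.

    Parameters
    ----------
    matrix
        Normalized expression, features x samples (at least 2 x 2).
    groups
        Optional sample_id -> response label, included in the report.
    up, down
        Declared up-/down-regulated feature ids for the summary counts.
    feature_classes
        Optional feature_id -> class (circ/lnc/mrna) for per-class counts.

    Returns
    -------
    dict with ``heatmap`` (z-scored matrix in leaf order),
    ``sample_linkage`` / ``feature_linkage`` (scipy linkage arrays whose
    third column holds merge heights), ``sample_order`` /
    ``feature_order`` and a ``summary`` DataFrame.
    """
    if matrix.shape[1] < 2:
        raise ValueError("at least two samples are required")
    if matrix.shape[0] < 2:
        raise ValueError("at least two features are required")
    vals = matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd

    feature_linkage = _corr_dist_linkage(z)
    sample_linkage = _corr_dist_linkage(z.T)
    feature_order = hierarchy.leaves_list(feature_linkage)
    sample_order = hierarchy.leaves_list(sample_linkage)

    heatmap = pd.DataFrame(
        z[np.ix_(feature_order, sample_order)],
        index=matrix.index[feature_order],
        columns=matrix.columns[sample_order],
    )

    up = set(up or ())
    down = set(down or ())
    rows = []
    if feature_classes is not None:
        fc = pd.Series(feature_classes)
        for cls in sorted(fc.unique()):
            ids = set(fc.index[fc == cls]) & set(matrix.index)
            rows.append(
                {
                    "class": cls,
                    "n_features": len(ids),
                    "n_up": len(ids & up),
                    "n_down": len(ids & down),
                }
            )
    else:
        ids = set(matrix.index)
        rows.append(
            {
                "class": "all",
                "n_features": len(ids),
                "n_up": len(ids & up),
                "n_down": len(ids & down),
            }
        )
    summary = pd.DataFrame(rows)

    report = {
        "heatmap": heatmap,
        "sample_linkage": sample_linkage,
        "feature_linkage": feature_linkage,
        "sample_order": list(matrix.columns[sample_order]),
        "feature_order": list(matrix.index[feature_order]),
        "summary": summary,
    }
    if groups is not None:
        report["groups"] = pd.Series(groups).reindex(
            report["sample_order"]
        )
    return report
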