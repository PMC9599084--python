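"""Circular-to-linear transcript ratio.

For a locus with ``bsj`` back-splice junction reads (circular transcript)
and ``fsj`` forward-splice junction reads (linear transcript), the ratio

    r = 2*bsj / (2*bsj + fsj)

lies in [0, 1]: 0 means purely linear expression, 1 purely circular.
The factor 2 accounts for a linear junction read being producible from
either side of the back-splice.  ``bsj = fsj = 0`` has no defined ratio
and is reported as missing (NaN), never as a number.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["circular_linear_ratio", "ratio_table"]


def circular_linear_ratio(bsj, fsj):
    """2*bsj/(2*bsj + fsj); NaN where both counts are zero.

    Accepts scalars or arrays; negative counts raise.
    """
    bsj_arr = np.asarray(bsj, dtype=float)
    fsj_arr = np.asarray(fsj, dtype=float)
    if np.any(bsj_arr < 0) or np.any(fsj_arr < 0):
        raise ValueError("bsj and fsj must be non-negative")
    denom = 2.0 * bsj_arr + fsj_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, 2.0 * bsj_arr / np.where(denom > 0, denom, 1.0),
                     np.nan)
    if np.isscalar(bsj) and np.isscalar(fsj):
        return float(r)
    return r


def ratio_table(
    bsj_counts: pd.DataFrame,
    fsj_counts: pd.DataFrame,
    groups: pd.Series | None = None,
    by: str = "cohort",
) -> pd.DataFrame:
    """Per-circRNA circular-to-linear ratios at a chosen aggregation scope.

    Parameters
    ----------
    bsj_counts, fsj_counts
        circRNA x sample count matrices sharing a sample namespace; loci
        present in only one input are flagged ``missing`` and get NaN.
    groups
        sample_id -> group label; required for ``by="group"``.
    by
        ``"cohort"`` pools all samples, ``"group"`` pools within each
        group, ``"sample"`` computes per-sample ratios.  Pooling sums BSJ
        and FSJ reads over the scope's samples before applying the
        formula.

    Returns
    -------
    DataFrame indexed by circ_id with one ratio column per scope plus a
    ``status`` column ({ok, missing, undefined}).
    """
    if by not in ("cohort", "group", "sample"):
        raise ValueError("by must be one of 'cohort', 'group', 'sample'")
    common = [c for c in bsj_counts.columns if c in set(fsj_counts.columns)]
    if not common:
        raise ValueError("aggregation scope has zero samples")
    all_ids = sorted(set(bsj_counts.index) | set(fsj_counts.index))
    shared = sorted(set(bsj_counts.index) & set(fsj_counts.index))
    n_missing = len(all_ids) - len(shared)
    if n_missing:
        logger.warning(
            "ratio_table: %d locus/loci present in only one input flagged "
            "missing", n_missing,
        )
    b = bsj_counts.reindex(index=shared, columns=common)
    f = fsj_counts.reindex(index=shared, columns=common)

    scopes: dict[str, list[str]]
    if by == "cohort":
        scopes = {"ratio": common}
    elif by == "sample":
        scopes = {s: [s] for s in common}
    else:
        if groups is None:
            raise ValueError("groups is required for by='group'")
        scopes = {}
        for g in sorted(pd.Series(groups).loc[common].unique()):
            cols = [s for s in common if groups[s] == g]
            if not cols:
                raise ValueError(f"group {g!r} has zero samples")
            scopes[g] = cols

    out = pd.DataFrame(index=pd.Index(all_ids, name="circ_id"))
    undefined = np.zeros(len(shared), dtype=bool)
    for name, cols in scopes.items():
        bs = b[cols].sum(axis=1).to_numpy()
        fs = f[cols].sum(axis=1).to_numpy()
        r = circular_linear_ratio(bs, fs)
        undefined |= np.isnan(r)
        out.loc[shared, name] = r
    status = pd.Series("missing", index=out.index)
    status.loc[shared] = "ok"
    status.loc[np.asarray(shared, dtype=object)[undefined]] = "undefined"
    n_undef = int(undefined.sum())
    if n_undef:
        logger.warning(
            "ratio_table: %d locus/loci with zero BSJ and FSJ reads in some "
            "scope reported as undefined", n_undef,
        )
    out["status"] = status
    return out
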