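"""Multi-caller circRNA consensus detection.

circRNA callers disagree on coordinate conventions (0- vs 1-based,
open vs closed intervals), so calls are first harmonized onto canonical
0-based half-open stranded intervals via per-caller offset profiles.
Harmonized calls are stacked into a (circRNA x sample x caller) read
tensor, merged into a consensus count matrix (per-cell median over the
callers supporting the circRNA), and filtered to the high-confidence set:
a circRNA is retained iff it was reported by at least ``min_callers``
callers and its consensus counts reach ``min_reads`` reads in at least
``min_samples`` samples.

The reads/samples condition is evaluated on merged consensus counts by
default (``reads_scope="merged"``); ``reads_scope="per_caller"`` instead
requires the condition to hold within at least ``min_callers`` callers
individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import DEFAULT_CALLER_PROFILES

logger = logging.getLogger(__name__)

__all__ = [
    "CALLER_OFFSET_PROFILES",
    "CallTensor",
    "ConsensusMatrix",
    "CircConsensus",
    "harmonize_calls",
    "build_call_tensor",
    "high_confidence_filter",
    "consensus_counts",
    "summarize_genome",
    "circ_key",
]

#: Shipped offset profiles for the five supported callers: the (start, end)
#: shift taking each caller's reported coordinates to canonical 0-based
#: half-open.
CALLER_OFFSET_PROFILES = dict(DEFAULT_CALLER_PROFILES)

_CALL_COLUMNS = [
    "caller_id", "sample_id", "chrom", "start", "end", "strand", "bsj_reads",
]


def circ_key(chrom, start, end, strand) -> str:
    """Canonical circRNA identifier ``chrom:start-end:strand``."""
    return f"{chrom}:{int(start)}-{int(end)}:{strand}"


def harmonize_calls(
    calls: pd.DataFrame,
    offset_profiles: dict[str, tuple[int, int]] | None = None,
    return_rejected: bool = False,
):
    """Shift every caller's coordinates onto the canonical convention.

    Parameters
    ----------
    calls
        Long call table with columns ``caller_id, sample_id, chrom,
        start, end, strand, bsj_reads`` in caller-native coordinates.
    offset_profiles
        Mapping caller -> (start_shift, end_shift); defaults to the
        shipped profiles for the five supported callers.
    return_rejected
        Also return the records invalid after shifting (start >= end or
        negative reads); these are always excluded and logged.

    Returns
    -------
    Harmonized DataFrame with an added canonical ``circ_id`` column (and
    the rejected records with a ``reject_reason`` column when requested).
    """
    profiles = dict(
        CALLER_OFFSET_PROFILES if offset_profiles is None else offset_profiles
    )
    missing = [c for c in _CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table is missing columns: {missing}")
    unknown = sorted(set(calls["caller_id"]) - set(profiles))
    if unknown:
        raise ValueError(
            f"no offset profile for caller(s) {unknown}; "
            f"known profiles: {sorted(profiles)}"
        )
    out = calls.copy()
    shifts = out["caller_id"].map({k: v[0] for k, v in profiles.items()})
    shifte = out["caller_id"].map({k: v[1] for k, v in profiles.items()})
    out["start"] = out["start"].astype(np.int64) + shifts.astype(np.int64)
    out["end"] = out["end"].astype(np.int64) + shifte.astype(np.int64)

    bad_interval = out["start"] >= out["end"]
    bad_reads = out["bsj_reads"] < 0
    bad = bad_interval | bad_reads
    if bad.any():
        rejected = out.loc[bad].copy()
        rejected["reject_reason"] = np.where(
            bad_interval[bad], "start >= end after shift", "negative bsj_reads"
        )
        logger.warning(
            "harmonize_calls: rejected %d record(s): %s",
            int(bad.sum()),
            rejected["reject_reason"].value_counts().to_dict(),
        )
        out = out.loc[~bad]
    else:
        rejected = out.iloc[0:0].copy()
        rejected["reject_reason"] = pd.Series(dtype=object)

    out = out.reset_index(drop=True)
    out["circ_id"] = [
        circ_key(c, s, e, st)
        for c, s, e, st in zip(
            out["chrom"], out["start"], out["end"], out["strand"]
        )
    ]
    if return_rejected:
        return out, rejected.reset_index(drop=True)
    return out


@dataclass
class CallTensor:
    """Dense circRNA x sample x caller BSJ-read tensor.

    Axes are sorted lexicographically so the tensor (and everything
    derived from it) is invariant to input row order.
    """

    values: np.ndarray  # (n_circ, n_sample, n_caller), int64
    circ_ids: list[str]
    sample_ids: list[str]
    caller_ids: list[str]

    def support(self) -> pd.Series:
        """Per-circRNA set of callers that reported it in any sample."""
        any_hit = self.values.sum(axis=1) > 0  # (circ, caller)
        callers = np.asarray(self.caller_ids, dtype=object)
        return pd.Series(
            [frozenset(callers[row]) for row in any_hit],
            index=pd.Index(self.circ_ids, name="circ_id"),
            name="caller_support",
        )

    def total_reads(self) -> int:
        return int(self.values.sum())


def build_call_tensor(
    harmonized: pd.DataFrame,
    sample_ids: list[str] | None = None,
    caller_ids: list[str] | None = None,
) -> CallTensor:
    """Stack harmonized calls into a dense tensor.

    Missing (circ, sample, caller) cells are zero; duplicate records for
    one cell are summed (split output lines from one caller).
    """
    if "circ_id" not in harmonized.columns:
        raise ValueError("input must be harmonized (circ_id column required)")
    circ_ids = sorted(harmonized["circ_id"].unique())
    if sample_ids is None:
        sample_ids = sorted(harmonized["sample_id"].unique())
    else:
        sample_ids = list(sample_ids)
    if caller_ids is None:
        caller_ids = sorted(harmonized["caller_id"].unique())
    else:
        caller_ids = list(caller_ids)
    ci = {c: i for i, c in enumerate(circ_ids)}
    si = {s: i for i, s in enumerate(sample_ids)}
    ki = {k: i for i, k in enumerate(caller_ids)}
    values = np.zeros((len(circ_ids), len(sample_ids), len(caller_ids)),
                      dtype=np.int64)
    ii = harmonized["circ_id"].map(ci).to_numpy()
    jj = harmonized["sample_id"].map(si).to_numpy()
    kk = harmonized["caller_id"].map(ki).to_numpy()
    np.add.at(values, (ii, jj, kk),
              harmonized["bsj_reads"].to_numpy(dtype=np.int64))
    return CallTensor(values, circ_ids, sample_ids, caller_ids)


@dataclass
class ConsensusMatrix:
    """Consensus BSJ counts (circRNA x sample) plus caller support sets."""

    counts: pd.DataFrame
    support: pd.Series = field(repr=False)

    def restrict(self, circ_ids) -> "ConsensusMatrix":
        ids = [c for c in self.counts.index if c in set(circ_ids)]
        return ConsensusMatrix(self.counts.loc[ids], self.support.loc[ids])


def consensus_counts(
    tensor: CallTensor, quantifier: str = "median"
) -> ConsensusMatrix:
    """Merge per-caller counts into one consensus count per cell.

    The consensus for (circ, sample) is the ``quantifier`` (median, mean,
    or max) of the counts across the callers that reported the circRNA
    *anywhere* — a supporting caller's zero in one sample still counts as
    an observation of zero.  Medians are rounded half to even; cells of
    circRNAs no caller reported are zero.
    """
    if tensor.values.size == 0:
        raise ValueError("call tensor is empty")
    reported = tensor.values.sum(axis=1) > 0  # (circ, caller)
    n_circ, n_sample, _ = tensor.values.shape
    out = np.zeros((n_circ, n_sample), dtype=np.int64)
    for i in range(n_circ):
        sel = reported[i]
        if not sel.any():
            continue
        block = tensor.values[i, :, sel]  # (n_sel, n_sample)
        if quantifier == "median":
            out[i] = np.round(np.median(block, axis=0)).astype(np.int64)
        elif quantifier == "mean":
            out[i] = np.round(block.mean(axis=0)).astype(np.int64)
        elif quantifier == "max":
            out[i] = block.max(axis=0)
        else:
            raise ValueError(f"unknown quantifier {quantifier!r}")
    counts = pd.DataFrame(
        out,
        index=pd.Index(tensor.circ_ids, name="circ_id"),
        columns=tensor.sample_ids,
    )
    return ConsensusMatrix(counts=counts, support=tensor.support())


def high_confidence_filter(
    tensor: CallTensor,
    min_reads: int = 2,
    min_samples: int = 2,
    min_callers: int = 3,
    reads_scope: str = "merged",
) -> list[str]:
    """Apply the high-confidence consensus filter; returns retained ids.

    Retains a circRNA iff (a) its caller-support set has at least
    ``min_callers`` members and (b) it shows at least ``min_reads`` BSJ
    reads in at least ``min_samples`` samples (default 2 reads /
    2 samples / 3 callers).  With the default ``reads_scope="merged"``,
    condition (b) is evaluated on the cell-wise *union of evidence*
    across callers (the maximum reported count): any caller attesting
    the reads satisfies the cell, which keeps the retained set monotone
    under added reads or callers — a robust-median merge would not be,
    since a new low-count caller joining the support set lowers cell
    medians.  (The exported consensus *quantification* still uses the
    ``quantifier`` median.)  With ``reads_scope="per_caller"``, (b) must
    instead hold within at least ``min_callers`` callers individually.
    """
    for name, v in (("min_reads", min_reads), ("min_samples", min_samples),
                    ("min_callers", min_callers)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if min_callers > len(tensor.caller_ids):
        raise ValueError(
            f"min_callers={min_callers} exceeds the {len(tensor.caller_ids)} "
            "callers present"
        )
    if reads_scope not in ("merged", "per_caller"):
        raise ValueError("reads_scope must be 'merged' or 'per_caller'")

    reported = tensor.values.sum(axis=1) > 0  # (circ, caller)
    n_support = reported.sum(axis=1)
    if reads_scope == "merged":
        evidence = tensor.values.max(axis=2)  # (circ, sample)
        n_good_samples = (evidence >= min_reads).sum(axis=1)
        keep = (n_support >= min_callers) & (n_good_samples >= min_samples)
    else:
        per_caller_ok = (
            (tensor.values >= min_reads).sum(axis=1) >= min_samples
        )  # (circ, caller)
        keep = (n_support >= min_callers) & (
            per_caller_ok.sum(axis=1) >= min_callers
        )
    return [c for c, k in zip(tensor.circ_ids, keep) if k]


def _annotation_lookup(annotation: pd.DataFrame | None) -> dict[str, str]:
    if annotation is None or len(annotation) == 0:
        return {}
    ann = annotation.copy()
    if "circ_id" not in ann.columns:
        needed = {"chrom", "start", "end", "strand"}
        if not needed.issubset(ann.columns):
            raise ValueError(
                "annotation must carry either a circ_id column or the "
                "chrom/start/end/strand key fields"
            )
        ann["circ_id"] = [
            circ_key(c, s, e, st)
            for c, s, e, st in zip(
                ann["chrom"], ann["start"], ann["end"], ann["strand"]
            )
        ]
    if "host_gene" not in ann.columns:
        raise ValueError("annotation must carry a host_gene column")
    return dict(zip(ann["circ_id"], ann["host_gene"]))


def summarize_genome(
    consensus: ConsensusMatrix,
    annotation: pd.DataFrame | None,
    groups: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Per-chromosome read totals by response group and host-gene ranking.

    ``groups`` maps sample_id -> response label.  circRNAs absent from the
    annotation are labeled ``novel`` and excluded from the gene ranking.
    """
    counts = consensus.counts
    missing = [s for s in counts.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing a group label: {missing}")
    lookup = _annotation_lookup(annotation)
    chroms = [cid.rsplit(":", 2)[0] for cid in counts.index]
    genes = [lookup.get(cid, "novel") for cid in counts.index]

    per_group = {}
    for g in sorted(groups.unique()):
        cols = [s for s in counts.columns if groups[s] == g]
        per_group[g] = counts[cols].sum(axis=1).to_numpy()
    chrom_df = pd.DataFrame({"chrom": chroms, **per_group})
    per_chrom = chrom_df.groupby("chrom", sort=True).sum()
    per_chrom["total_reads"] = per_chrom.sum(axis=1)
    per_chrom["n_circ"] = pd.Series(chroms).value_counts().reindex(
        per_chrom.index, fill_value=0
    )

    gene_df = pd.DataFrame({"host_gene": genes, **per_group})
    gene_df = gene_df[gene_df["host_gene"] != "novel"]
    if len(gene_df):
        gene_rank = gene_df.groupby("host_gene", sort=False).sum()
        gene_rank["total_reads"] = gene_rank.sum(axis=1)
        gene_rank = gene_rank.sort_values("total_reads", ascending=False)
    else:
        gene_rank = pd.DataFrame(
            columns=list(per_group) + ["total_reads"]
        ).rename_axis("host_gene")
    return {"per_chromosome": per_chrom.reset_index(),
            "host_gene_ranking": gene_rank.reset_index()}


class CircConsensus(BaseEstimator):
    """Harmonize, merge and filter multi-caller circRNA calls.

    A transformer in the scikit-learn idiom: :meth:`fit` consumes the raw
    per-caller call table, :meth:`transform` returns the consensus BSJ
    count matrix restricted to the high-confidence set.

    Parameters
    ----------
    min_reads, min_samples, min_callers
        High-confidence thresholds (defaults 2 reads, 2 samples,
        3 callers).
    reads_scope
        ``"merged"`` (default) evaluates the reads/samples condition on
        merged consensus counts; ``"per_caller"`` within each caller.
    quantifier
        Cross-caller merge statistic (``median`` default).
    offset_profiles
        Caller coordinate conventions; ``None`` uses the shipped five.

    Attributes
    ----------
    harmonized_ : pd.DataFrame
        Calls on canonical coordinates (rejects excluded).
    rejected_ : pd.DataFrame
        Records dropped during harmonization, with reasons.
    tensor_ : CallTensor
    consensus_ : ConsensusMatrix
        All harmonized circRNAs (pre-filter).
    retained_keys_ : list[str]
        The high-confidence circRNA ids.
    matrix_ : pd.DataFrame
        Consensus counts restricted to the high-confidence set.
    support_ : pd.Series
        Caller-support set per circRNA.
    """

    def __init__(
        self,
        min_reads: int = 2,
        min_samples: int = 2,
        min_callers: int = 3,
        reads_scope: str = "merged",
        quantifier: str = "median",
        offset_profiles: dict | None = None,
    ):
        self.min_reads = min_reads
        self.min_samples = min_samples
        self.min_callers = min_callers
        self.reads_scope = reads_scope
        self.quantifier = quantifier
        self.offset_profiles = offset_profiles

    def fit(self, X: pd.DataFrame, y=None, sample_ids=None):
        """Fit on a raw per-caller call table (caller-native coordinates)."""
        self.harmonized_, self.rejected_ = harmonize_calls(
            X, self.offset_profiles, return_rejected=True
        )
        self.tensor_ = build_call_tensor(self.harmonized_,
                                         sample_ids=sample_ids)
        self.consensus_ = consensus_counts(self.tensor_, self.quantifier)
        self.support_ = self.consensus_.support
        self.retained_keys_ = high_confidence_filter(
            self.tensor_,
            min_reads=self.min_reads,
            min_samples=self.min_samples,
            min_callers=self.min_callers,
            reads_scope=self.reads_scope,
        )
        self.matrix_ = self.consensus_.counts.loc[self.retained_keys_]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the high-confidence consensus count matrix."""
        if not hasattr(self, "matrix_"):
            raise ValueError("CircConsensus is not fitted yet")
        if X is not None:
            return self.__class__(**self.get_params()).fit(X).matrix_
        return self.matrix_

    def fit_transform(self, X, y=None, **kw) -> pd.DataFrame:
        return self.fit(X, **kw).transform()

    def summarize(self, annotation: pd.DataFrame | None, groups: pd.Series):
        """Genomic summaries of the high-confidence set (see
        :func:`summarize_genome`)."""
        return summarize_genome(
            self.consensus_.restrict(self.retained_keys_), annotation, groups
        )
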