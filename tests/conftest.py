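import warnings

import numpy as np
import pandas as pd
import pytest

from cerna_icb import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_circ_loci=60, n_lnc=80, n_mrna=120, seed=3)


@pytest.fixture(scope="session")
def sim(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(small_config)


def random_call_fixture(rng: np.random.Generator, n_circ=None, n_samples=12,
                        n_callers=5) -> pd.DataFrame:
    """Random harmonized-style call table (canonical coordinates)."""
    if n_circ is None:
        n_circ = int(rng.integers(20, 120))
    circ = [f"chr{rng.integers(1, 23)}:{i * 1000}-{i * 1000 + 500}:+"
            for i in range(n_circ)]
    samples = [f"s{j}" for j in range(n_samples)]
    callers = [f"caller{k}" for k in range(n_callers)]
    rows = []
    for cid in circ:
        for k in callers:
            if rng.random() < 0.5:
                continue
            for s in samples:
                reads = int(rng.poisson(2))
                if reads:
                    chrom, span, strand = cid.rsplit(":", 2)
                    a, b = span.split("-")
                    rows.append((k, s, chrom, int(a), int(b), strand, reads,
                                 cid))
    return pd.DataFrame(
        rows,
        columns=["caller_id", "sample_id", "chrom", "start", "end", "strand",
                 "bsj_reads", "circ_id"],
    )


def brute_force_filter(tensor, min_reads=2, min_samples=2, min_callers=3,
                       reads_scope="merged"):
    """Triple-loop reimplementation of the high-confidence filter."""
    retained = []
    for i, cid in enumerate(tensor.circ_ids):
        support = [
            k for k in range(len(tensor.caller_ids))
            if any(tensor.values[i, j, k] > 0
                   for j in range(len(tensor.sample_ids)))
        ]
        if len(support) < min_callers:
            continue
        if reads_scope == "merged":
            good = 0
            for j in range(len(tensor.sample_ids)):
                evidence = max(
                    tensor.values[i, j, k]
                    for k in range(len(tensor.caller_ids))
                )
                if evidence >= min_reads:
                    good += 1
            if good >= min_samples:
                retained.append(cid)
        else:
            ok = 0
            for k in support:
                good = sum(
                    tensor.values[i, j, k] >= min_reads
                    for j in range(len(tensor.sample_ids))
                )
                if good >= min_samples:
                    ok += 1
            if ok >= min_callers:
                retained.append(cid)
    return retained
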