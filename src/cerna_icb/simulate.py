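"""Seeded synthetic-cohort generator with exported ground truth.

Every stage of the analysis (caller consensus, circular-to-linear ratio,
differential expression, ceRNA network, survival risk score) consumes
data this module can generate with planted, recorded effects:

* a two-group cohort (responders / non-responders to checkpoint blockade),
* per-caller back-splice-junction call tables with caller-specific
  coordinate conventions and per-(locus, caller) dropout,
* negative-binomial count matrices (circRNA BSJ, lncRNA, mRNA) with a
  planted fraction of two-group effects of known log2 fold change,
* miRNA-interaction tables in which planted ceRNA--miRNA--mRNA triples
  carry mRNA-side prediction support of at least five of seven tools,
* exponential survival times whose hazard depends on a latent
  coefficient-weighted signature of the planted features.

All randomness flows from one integer master seed; each stage draws from
an independent substream keyed by a CRC-32 hash of the stage label, so
stages are individually reproducible.

Counts use the NB2 parameterization: variance = mean + dispersion * mean^2.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_circ_calls",
    "simulate_expression",
    "simulate_interactions",
    "simulate_survival",
    "simulate_all",
    "latent_risk_signal",
]

#: Fraction of a locus's true BSJ reads each caller recovers.  Binomial
#: thinning of an NB count is again NB, so per-caller counts stay NB.
CALLER_EFFICIENCY = 0.9


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG substream for one generator stage.

    The substream is seeded by the pair (master seed, CRC-32 of the stage
    label), so any stage can be re-run in isolation and different stages
    never share a stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """NB2 sample with variance mean + dispersion*mean^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        raise ConfigError(f"nb_dispersion must be > 0, got {dispersion!r}")
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# cohort

def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Sample table: id, response label and total linear mapped reads.

    Sequencing depth (``total_linear_mapped_reads``) varies log-normally
    around 2e7 so that size-factor anchoring downstream is exercised.
    """
    config.validate()
    rng = substream(config.seed, "cohort")
    n = config.n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    response = (["responder"] * config.n_responders
                + ["non-responder"] * config.n_nonresponders)
    depth = np.round(2e7 * rng.lognormal(mean=0.0, sigma=0.35, size=n)).astype(
        np.int64
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "response": response,
            "total_linear_mapped_reads": depth,
        }
    )


def _depth_factor(cohort: pd.DataFrame) -> np.ndarray:
    """Per-sample depth factors, geometric mean 1."""
    totals = cohort["total_linear_mapped_reads"].to_numpy(dtype=float)
    return totals / np.exp(np.mean(np.log(totals)))


def _plant_de(
    rng: np.random.Generator, feature_ids: list[str], config: SimConfig
) -> pd.DataFrame:
    """Pick the planted DE features and their signed log2 fold changes."""
    n = len(feature_ids)
    k = int(round(config.de_fraction * n))
    if config.de_fraction > 0 and k < 1:
        warnings.warn(
            "de_fraction * n_features < 1: no features planted",
            UserWarning,
            stacklevel=3,
        )
    chosen = sorted(rng.choice(n, size=k, replace=False)) if k else []
    direction = rng.choice([-1.0, 1.0], size=k)
    return pd.DataFrame(
        {
            "feature_id": [feature_ids[i] for i in chosen],
            "log2fc": direction * config.planted_log2fc,
        }
    )


def _group_mean_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    de: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SimConfig,
    mean_scale: float,
) -> np.ndarray:
    """Expected counts per (feature, sample): base mean x group effect x depth."""
    n_feat = len(feature_ids)
    base = mean_scale * rng.lognormal(mean=0.0, sigma=0.6, size=n_feat)
    lfc = pd.Series(0.0, index=feature_ids)
    if len(de):
        lfc.loc[de["feature_id"].to_numpy()] = de["log2fc"].to_numpy()
    lfc = lfc.to_numpy()
    is_resp = (cohort["response"] == "responder").to_numpy()
    # symmetric split keeps the overall mean scale unchanged
    group_mult = np.where(is_resp[None, :], 2.0 ** (lfc[:, None] / 2.0),
                          2.0 ** (-lfc[:, None] / 2.0))
    depth = _depth_factor(cohort)
    return base[:, None] * group_mult * depth[None, :]


# ---------------------------------------------------------------------------
# circRNA calls

_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def simulate_circ_calls(
    config: SimConfig, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-caller BSJ call tables plus linear FSJ counts and ground truth.

    Returns ``(calls, fsj, registry, true_bsj, circ_de)``:

    calls
        Long table of caller observations with columns
        ``caller_id, sample_id, chrom, start, end, strand, bsj_reads`` in
        each *caller's own* coordinate convention (the inverse of its
        offset profile); zero-count observations are not emitted, and a
        (locus, caller) pair is entirely absent with probability
        ``1 - caller_detection_prob``.
    fsj
        Forward-splice-junction counts, loci x samples.
    registry
        Canonical locus registry (0-based half-open, stranded).
    true_bsj
        Latent per-sample true BSJ counts (loci x samples); each caller
        reports a binomial thinning of these.
    circ_de
        Planted two-group effects on BSJ means (feature_id, log2fc).
    """
    config.validate()
    if len(cohort) == 0:
        raise ConfigError("cohort must be nonempty")
    rng = substream(config.seed, "circ_calls")

    n_loci = config.n_circ_loci
    chrom = rng.choice(_CHROMS, size=n_loci)
    start = rng.integers(10_000, 200_000_000, size=n_loci)
    length = rng.integers(200, 5_000, size=n_loci)
    end = start + length
    strand = rng.choice(["+", "-"], size=n_loci)
    circ_ids = [
        f"{c}:{s}-{e}:{st}" for c, s, e, st in zip(chrom, start, end, strand)
    ]
    registry = pd.DataFrame(
        {
            "circ_id": circ_ids,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
        }
    )

    circ_de = _plant_de(rng, circ_ids, config)
    circ_de.insert(1, "matrix", "circ")

    # latent true BSJ counts; BSJ libraries are shallower than linear ones
    mu = _group_mean_matrix(rng, circ_ids, circ_de, cohort, config,
                            mean_scale=0.3 * config.mean_expression)
    true_bsj = pd.DataFrame(
        _nb_draw(rng, mu, config.nb_dispersion),
        index=pd.Index(circ_ids, name="circ_id"),
        columns=cohort["sample_id"].to_numpy(),
    )

    # linear FSJ counts at the same loci (independent linear expression)
    fsj_mu = _group_mean_matrix(
        rng, circ_ids, circ_de.iloc[0:0], cohort, config,
        mean_scale=config.mean_expression,
    )
    fsj = pd.DataFrame(
        _nb_draw(rng, fsj_mu, config.nb_dispersion),
        index=pd.Index(circ_ids, name="circ_id"),
        columns=cohort["sample_id"].to_numpy(),
    )

    callers = config.callers
    detected = rng.random((n_loci, len(callers))) < config.caller_detection_prob

    rows = []
    sample_ids = cohort["sample_id"].to_numpy()
    counts = true_bsj.to_numpy()
    for k, caller in enumerate(callers):
        ds, de_ = config.caller_offset_profile[caller]
        # caller coordinates are the inverse shift of the profile
        c_start = start - ds
        c_end = end - de_
        present = np.flatnonzero(detected[:, k])
        if present.size == 0:
            continue
        observed = rng.binomial(counts[present], CALLER_EFFICIENCY)
        for row_i, locus in enumerate(present):
            for j, sample in enumerate(sample_ids):
                reads = int(observed[row_i, j])
                if reads == 0:
                    continue
                rows.append(
                    (
                        caller,
                        sample,
                        chrom[locus],
                        int(c_start[locus]),
                        int(c_end[locus]),
                        strand[locus],
                        reads,
                    )
                )
    calls = pd.DataFrame(
        rows,
        columns=[
            "caller_id", "sample_id", "chrom", "start", "end", "strand",
            "bsj_reads",
        ],
    )
    return calls, fsj, registry, true_bsj, circ_de


# ---------------------------------------------------------------------------
# expression matrices

def simulate_expression(
    config: SimConfig, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """lncRNA and mRNA count matrices with planted two-group effects.

    Returns ``(lnc_counts, mrna_counts, de_truth)``; ``de_truth`` has one
    row per planted feature with its matrix of origin and signed log2FC.
    """
    config.validate()
    if cohort["response"].nunique() < 2:
        raise ConfigError("cohort must contain both response groups")
    rng = substream(config.seed, "expression")
    sample_ids = cohort["sample_id"].to_numpy()

    matrices = {}
    truth = []
    for cls, n_feat in (("lnc", config.n_lnc), ("mrna", config.n_mrna)):
        ids = [f"{cls}_{i + 1:04d}" for i in range(n_feat)]
        de = _plant_de(rng, ids, config)
        de.insert(1, "matrix", cls)
        truth.append(de)
        mu = _group_mean_matrix(rng, ids, de, cohort, config,
                                mean_scale=config.mean_expression)
        matrices[cls] = pd.DataFrame(
            _nb_draw(rng, mu, config.nb_dispersion),
            index=pd.Index(ids, name="feature_id"),
            columns=sample_ids,
        )
    de_truth = pd.concat(truth, ignore_index=True)
    return matrices["lnc"], matrices["mrna"], de_truth


# ---------------------------------------------------------------------------
# miRNA interactions

def simulate_interactions(
    config: SimConfig,
    circ_ids: list[str],
    lnc_ids: list[str],
    mrna_ids: list[str],
    de_features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Interaction tables with planted high-support ceRNA-miRNA-mRNA triples.

    Planted triples connect a planted DE ceRNA (circRNA or lncRNA) to a
    planted DE mRNA through a dedicated miRNA, with mRNA-side tool support
    drawn from {5, 6, 7} so they survive the five-tool consensus filter.
    Decoy interactions draw support from ``config.support_distribution``.

    Returns ``(circ_mirna, lnc_mirna, mrna_mirna, planted_triples)``.
    """
    config.validate()
    id_sets = [set(circ_ids), set(lnc_ids), set(mrna_ids)]
    for a in range(3):
        for b in range(a + 1, 3):
            if id_sets[a] & id_sets[b]:
                raise ConfigError("feature id sets must be disjoint")
    rng = substream(config.seed, "interactions")
    mirna_ids = [f"hsa-miR-{i + 1:04d}" for i in range(config.n_mirna)]

    # triples pair direction-concordant DE features: a sponge and its
    # de-repressed target move together, so the planted edge carries the
    # positive expression correlation the network's retention rule expects
    ce_mask = de_features["matrix"].isin(["circ", "lnc"])
    mrna_mask = de_features["matrix"] == "mrna"
    de_ce_by_dir = {
        sign: de_features.loc[
            ce_mask & (np.sign(de_features["log2fc"]) == sign), "feature_id"
        ].tolist()
        for sign in (-1.0, 1.0)
    }
    de_mrna_by_dir = {
        sign: de_features.loc[
            mrna_mask & (np.sign(de_features["log2fc"]) == sign),
            "feature_id",
        ].tolist()
        for sign in (-1.0, 1.0)
    }
    usable_dirs = [s for s in (-1.0, 1.0)
                   if de_ce_by_dir[s] and de_mrna_by_dir[s]]
    de_ce = [f for s in usable_dirs for f in de_ce_by_dir[s]]
    de_mrna = [f for s in usable_dirs for f in de_mrna_by_dir[s]]

    n_triples = min(config.n_planted_triples, len(de_ce) * max(len(de_mrna), 1),
                    config.n_mirna)
    planted = []
    if n_triples and de_ce and de_mrna:
        triple_mirnas = rng.choice(mirna_ids, size=n_triples, replace=False)
        for m in triple_mirnas:
            sign = usable_dirs[int(rng.integers(len(usable_dirs)))]
            ce_pool = de_ce_by_dir[sign]
            g_pool = de_mrna_by_dir[sign]
            c = ce_pool[int(rng.integers(len(ce_pool)))]
            g = g_pool[int(rng.integers(len(g_pool)))]
            support = int(rng.integers(5, config.n_pred_tools + 1))
            planted.append((c, m, g, support))
    planted_df = pd.DataFrame(
        planted, columns=["cerna_id", "mirna_id", "mrna_id", "support"]
    )

    def decoy_rows(ids: list[str], cls: str, with_support: bool) -> list[tuple]:
        rows = []
        supports = np.arange(1, config.n_pred_tools + 1)
        probs = np.asarray(config.support_distribution, dtype=float)
        for fid in ids:
            for _ in range(rng.poisson(1.5)):
                m = mirna_ids[int(rng.integers(config.n_mirna))]
                if with_support:
                    s = int(rng.choice(supports, p=probs))
                    rows.append((fid, m, cls, s))
                else:
                    rows.append((fid, m, cls))
        return rows

    circ_tab = pd.DataFrame(
        decoy_rows(circ_ids, "circ", False),
        columns=["source_id", "mirna_id", "source_class"],
    )
    lnc_tab = pd.DataFrame(
        decoy_rows(lnc_ids, "lnc", False),
        columns=["source_id", "mirna_id", "source_class"],
    )
    mrna_tab = pd.DataFrame(
        decoy_rows(mrna_ids, "mrna", True),
        columns=["source_id", "mirna_id", "source_class", "support"],
    )

    if len(planted_df):
        circ_set = set(circ_ids)
        ce_rows = [
            (r.cerna_id, r.mirna_id,
             "circ" if r.cerna_id in circ_set else "lnc")
            for r in planted_df.itertuples()
        ]
        ce_df = pd.DataFrame(
            ce_rows, columns=["source_id", "mirna_id", "source_class"]
        )
        circ_tab = pd.concat(
            [circ_tab, ce_df[ce_df["source_class"] == "circ"]],
            ignore_index=True,
        )
        lnc_tab = pd.concat(
            [lnc_tab, ce_df[ce_df["source_class"] == "lnc"]],
            ignore_index=True,
        )
        planted_mrna = planted_df.rename(
            columns={"mrna_id": "source_id"}
        )[["source_id", "mirna_id", "support"]]
        planted_mrna.insert(2, "source_class", "mrna")
        # planted rows win over colliding decoys so support is never downgraded
        mrna_tab = pd.concat([planted_mrna, mrna_tab], ignore_index=True)

    for tab in (circ_tab, lnc_tab):
        tab.drop_duplicates(["source_id", "mirna_id"], inplace=True)
        tab.reset_index(drop=True, inplace=True)
    mrna_tab.drop_duplicates(["source_id", "mirna_id"], keep="first",
                             inplace=True)
    mrna_tab.reset_index(drop=True, inplace=True)
    return circ_tab, lnc_tab, mrna_tab, planted_df.drop(columns=["support"])


# ---------------------------------------------------------------------------
# survival

def latent_risk_signal(
    expression: pd.DataFrame,
    de_features: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.DataFrame]:
    """Coefficient-weighted planted-signature signal, one value per sample.

    ``expression`` is features x samples (raw counts, any of the planted
    matrices concatenated).  Each planted feature receives a coefficient
    whose sign matches its planted direction; the signal is the weighted
    mean of z-scored log2(count + 1) values, standardized across samples.
    """
    planted = de_features["feature_id"].tolist()
    planted = [f for f in planted if f in expression.index]
    if not planted:
        raise ConfigError("no planted features available for the risk signal")
    sub = de_features.set_index("feature_id").loc[planted]
    coefs = np.sign(sub["log2fc"].to_numpy()) * np.abs(
        rng.normal(0.75, 0.25, size=len(planted))
    )
    logx = np.log2(expression.loc[planted].to_numpy(dtype=float) + 1.0)
    z = (logx - logx.mean(axis=1, keepdims=True))
    sd = logx.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    raw = coefs @ z / np.sqrt(len(planted))
    raw = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)
    signal = pd.Series(raw, index=expression.columns, name="risk_signal")
    coef_table = pd.DataFrame(
        {"feature_id": planted, "coefficient": coefs}
    )
    return signal, coef_table


def simulate_survival(config: SimConfig, signal: pd.Series) -> pd.DataFrame:
    """OS and PFS times/events with hazard tied to the latent signal.

    Event times are exponential with hazard
    ``baseline_hazard * exp(signature_hazard_beta * signal)`` (PFS uses
    twice the baseline hazard); censoring strikes each endpoint
    independently with probability ``censor_rate``, replacing the event
    time by a uniform fraction of it.
    """
    config.validate()
    rng = substream(config.seed, "survival")
    signal = pd.Series(signal)
    out = {"sample_id": signal.index.to_numpy()}
    hazard_scale = np.exp(config.signature_hazard_beta
                          * signal.to_numpy(dtype=float))
    for endpoint, base in (("os", config.baseline_hazard),
                           ("pfs", 2.0 * config.baseline_hazard)):
        rate = base * hazard_scale
        t = rng.exponential(1.0 / rate)
        censored = rng.random(len(t)) < config.censor_rate
        t = np.where(censored, t * rng.uniform(size=len(t)), t)
        t = np.maximum(t, 1e-6)
        out[f"{endpoint}_time"] = t
        out[f"{endpoint}_event"] = (~censored).astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# full bundle

@dataclass
class SimulatedCohort:
    """One synthetic dataset plus its exhaustive ground-truth tables."""

    config: SimConfig
    samples: pd.DataFrame          # cohort + survival columns
    calls: pd.DataFrame            # per-caller BSJ observations
    fsj: pd.DataFrame              # loci x samples linear FSJ counts
    lnc_counts: pd.DataFrame
    mrna_counts: pd.DataFrame
    circ_mirna: pd.DataFrame
    lnc_mirna: pd.DataFrame
    mrna_mirna: pd.DataFrame
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def true_bsj(self) -> pd.DataFrame:
        return self.truth["true_bsj"]

    def write(self, outdir) -> dict[str, str]:
        """Dump all tables as TSV (+ config YAML); returns name -> path."""
        import pathlib

        import yaml

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def dump(name: str, df: pd.DataFrame, index: bool) -> None:
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=index)
            paths[name] = str(p)

        dump("samples", self.samples, False)
        dump("circ_calls", self.calls, False)
        dump("fsj_counts", self.fsj, True)
        dump("lnc_counts", self.lnc_counts, True)
        dump("mrna_counts", self.mrna_counts, True)
        dump("circ_mirna", self.circ_mirna, False)
        dump("lnc_mirna", self.lnc_mirna, False)
        dump("mrna_mirna", self.mrna_mirna, False)
        for key, df in self.truth.items():
            dump(f"truth_{key}", df, key == "true_bsj")
        cfg_path = outdir / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        paths["config"] = str(cfg_path)
        return paths


def simulate_all(config: SimConfig) -> SimulatedCohort:
    """Run every generator stage and assemble the full bundle."""
    cohort = simulate_cohort(config)
    calls, fsj, registry, true_bsj, circ_de = simulate_circ_calls(
        config, cohort
    )
    lnc, mrna, expr_de = simulate_expression(config, cohort)
    de_truth = pd.concat([circ_de, expr_de], ignore_index=True)
    circ_mir, lnc_mir, mrna_mir, triples = simulate_interactions(
        config,
        circ_ids=list(true_bsj.index),
        lnc_ids=list(lnc.index),
        mrna_ids=list(mrna.index),
        de_features=de_truth,
    )
    # the signature driving survival lives on the ceRNA side (circ + lnc)
    ce_expr = pd.concat([true_bsj, lnc])
    ce_truth = de_truth[de_truth["matrix"].isin(["circ", "lnc"])]
    signal, coef_table = latent_risk_signal(
        ce_expr, ce_truth, substream(config.seed, "signal")
    )
    surv = simulate_survival(config, signal)
    samples = cohort.merge(surv, on="sample_id", validate="1:1")
    truth = {
        "de_features": de_truth,
        "planted_triples": triples,
        "registry": registry,
        "true_bsj": true_bsj,
        "risk_signal": signal.rename_axis("sample_id").reset_index(),
        "signature_coefficients": coef_table,
    }
    return SimulatedCohort(
        config=config,
        samples=samples,
        calls=calls,
        fsj=fsj,
        lnc_counts=lnc,
        mrna_counts=mrna,
        circ_mirna=circ_mir,
        lnc_mirna=lnc_mir,
        mrna_mirna=mrna_mir,
        truth=truth,
    )
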