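"""Synthetic bulk RNA-seq cohort generator with planted ground truth.

Emulates the study design every downstream stage expects: a tumor/normal
colon-cancer-style cohort with negative-binomial counts, planted
up/down-regulated genes, lncRNA-mRNA pairs co-expressed through a shared
log-scale latent factor, transcript sequences with reverse-complement
blocks embedded in a subset of those pairs, proportional-hazards
survival times driven by a known coefficient vector on signature
lncRNAs, and toy miRNA-target / pathogenic-gene tables.  Everything is
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_sequences",
    "simulate_survival",
    "write_cohort",
]

_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Sample sizes default to the reference colon adenocarcinoma cohort
    (451 tumor, 41 adjacent normal); feature counts default to a
    realistically sized but tractable transcriptome slice.  ``beta_true``
    entries are per-SD log hazard ratios applied to z-scored log2-CPM of
    the signature lncRNAs.
    """

    n_tumor: int = 451
    n_normal: int = 41
    n_mrna: int = 2000
    n_lnc: int = 500
    de_fraction: float = 0.1
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.1
    n_coreg_pairs: int = 50
    coreg_sigma: float = 0.7
    complementary_fraction: float = 0.3
    signature_size: int = 6
    beta_true: tuple = (0.5, 0.5, 0.5, -0.5, 0.5, -0.5)
    baseline_hazard: float = 0.0015  # events per day
    censor_rate: float = 0.7
    stage_slope: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tumor, self.n_normal, self.n_mrna, self.n_lnc) < 0:
            raise ValueError("counts must be non-negative")
        for name in ("de_fraction", "complementary_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.beta_true) != self.signature_size:
            raise ValueError("len(beta_true) must equal signature_size")
        if self.signature_size > self.n_lnc:
            raise ValueError("signature_size exceeds n_lnc")
        if self.n_coreg_pairs > min(self.n_mrna, self.n_lnc):
            raise ValueError("n_coreg_pairs exceeds available disjoint pairs")


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame  # features x samples, integer
    sample_sheet: pd.DataFrame
    feature_class: pd.Series
    transcripts: dict  # feature id -> {transcript id -> sequence}
    lnc_mir_targets: pd.DataFrame
    mrna_mir_targets: pd.DataFrame
    pathogenic_genes: list
    truth: dict


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_sequences(
    n_pairs: int,
    complementarity: float,
    length_range: tuple = (50, 120),
    seed: int = 0,
    block_length: int = 16,
    gc_block: bool = False,
):
    """Random RNA pairs, a fraction of which carry a planted complementary block.

    For planted pairs, a ``block_length`` stretch of the first partner is
    embedded reverse-complemented in the second; non-planted pairs are
    i.i.d. uniform over {A, C, G, U}.  Returns
    ``(sequences, complementary_pairs)`` where sequences maps
    ``M{i}``/``L{i}`` ids to sequences.
    """
    if not 0 <= complementarity <= 1:
        raise ValueError("complementarity must lie in [0, 1]")
    lo, hi = length_range
    if lo < 20:
        raise ValueError("sequence lengths must be at least 20")
    rng = np.random.default_rng(seed)
    n_comp = int(round(complementarity * n_pairs))
    seqs: dict[str, str] = {}
    planted = set()
    for i in range(n_pairs):
        la = int(rng.integers(lo, hi + 1))
        lb = int(rng.integers(lo, hi + 1))
        a = _random_seq(rng, la)
        b = _random_seq(rng, lb)
        if i < n_comp:
            blk = "G" * block_length if gc_block else a[: min(block_length, la)]
            pos = int(rng.integers(0, lb - len(blk) + 1)) if lb > len(blk) else 0
            b = (b[:pos] + _revcomp(blk) + b[pos + len(blk):])[:lb]
            planted.add((f"M{i}", f"L{i}"))
        seqs[f"M{i}"] = a
        seqs[f"L{i}"] = b
    return seqs, planted


def _censor(time: np.ndarray, censor_rate: float, rng: np.random.Generator):
    """Independent uniform(0, tau) censoring with tau bisected to the target rate."""
    n = time.size
    if censor_rate <= 0:
        return time, np.ones(n, dtype=int)
    if censor_rate >= 1:
        return time * rng.uniform(0, 1, size=n), np.zeros(n, dtype=int)

    def expected(tau):  # P(C < T) with C ~ U(0, tau)
        return float(np.mean(np.minimum(time / tau, 1.0)))

    lo, hi = float(time.min()) * 1e-3, float(time.max()) * 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    c = rng.uniform(0, tau, size=n)
    event = (time <= c).astype(int)
    observed = np.minimum(time, c)
    return observed, event


def simulate_survival(
    expr,
    beta_true: pd.Series,
    baseline_hazard: float = 0.0015,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential PH survival from an expression matrix and true coefficients.

    ``expr`` is features x samples (DataFrame or ExpressionMatrix);
    ``beta_true`` is indexed by feature ids present in ``expr``.  Hazard
    for sample i is ``baseline_hazard * exp(sum_j beta_j e_ij)`` with the
    expression values used exactly as supplied.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if isinstance(expr, pd.DataFrame):
        values = expr
    elif hasattr(expr, "values") and isinstance(expr.values, pd.DataFrame):
        values = expr.values
    else:
        raise TypeError("expr must be a DataFrame or ExpressionMatrix")
    beta_true = pd.Series(beta_true)
    missing = beta_true.index.difference(values.index)
    if len(missing):
        raise ValueError(f"beta_true features missing from expr: {list(missing)}")
    rng = np.random.default_rng(seed)
    lp = beta_true.to_numpy() @ values.loc[beta_true.index].to_numpy()
    lp = lp - lp.mean()
    hazard = baseline_hazard * np.exp(lp)
    t = rng.exponential(1.0 / hazard)
    obs, event = _censor(t, censor_rate, rng)
    return pd.DataFrame(
        {"os_days": np.maximum(obs, 1e-9), "event": event, "true_lp": lp},
        index=values.columns,
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort with its ground-truth manifest."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_feat = cfg.n_mrna + cfg.n_lnc
    n_samp = cfg.n_tumor + cfg.n_normal

    mrna_ids = [f"MRNA{i:05d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"LNC{i:05d}" for i in range(cfg.n_lnc)]
    features = pd.Index(mrna_ids + lnc_ids)
    feature_class = pd.Series(
        ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lnc, index=features
    )
    samples = [f"T{i:04d}" for i in range(cfg.n_tumor)] + [
        f"N{i:04d}" for i in range(cfg.n_normal)
    ]
    is_tumor = np.array([s.startswith("T") for s in samples])

    # gene-specific base means, log-normal; lncRNAs lower expressed
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_feat)
    base[cfg.n_mrna:] *= 0.5
    base = np.maximum(base, 1.0)

    # planted differential expression, half up / half down per class,
    # chosen among reasonably expressed genes so effects are detectable
    de_up, de_down = [], []
    for cls_ids, start in ((mrna_ids, 0), (lnc_ids, cfg.n_mrna)):
        n_de = int(round(cfg.de_fraction * len(cls_ids)))
        eligible = np.where(base[start : start + len(cls_ids)] >= 20)[0]
        n_de = min(n_de, len(eligible))
        chosen = rng.choice(eligible, size=n_de, replace=False) + start
        half = n_de // 2
        de_up.extend(features[chosen[:half]])
        de_down.extend(features[chosen[half:]])
    de_up, de_down = list(de_up), list(de_down)

    # planted co-regulated pairs are drawn from the dysregulated genes
    # when possible (the downstream correlation block only sees those),
    # falling back to the remaining pool; members get their base
    # expression floored so the rank correlation is visible over noise
    def _pick_pairs(pool_de, pool_rest, k):
        pool = list(pool_de) + [i for i in pool_rest if i not in set(pool_de)]
        return [pool[i] for i in range(k)]

    de_idx = features.get_indexer(de_up + de_down)
    de_m_idx = [i for i in de_idx if i < cfg.n_mrna]
    de_l_idx = [i for i in de_idx if i >= cfg.n_mrna]
    pair_m = _pick_pairs(
        rng.permutation(de_m_idx) if de_m_idx else [],
        rng.permutation(cfg.n_mrna),
        cfg.n_coreg_pairs,
    )
    pair_l = _pick_pairs(
        rng.permutation(de_l_idx) if de_l_idx else [],
        rng.permutation(np.arange(cfg.n_mrna, n_feat)),
        cfg.n_coreg_pairs,
    )
    coreg_pairs = [(features[m], features[l]) for m, l in zip(pair_m, pair_l)]
    for idx in list(pair_m) + list(pair_l):
        base[idx] = max(base[idx], 100.0)

    # per-sample mean matrix: DE folds, then shared latent co-regulation
    mu = np.tile(base[:, None], (1, n_samp)).astype(float)
    fold = 2.0 ** cfg.lfc_effect
    up_idx = features.get_indexer(de_up)
    down_idx = features.get_indexer(de_down)
    mu[np.ix_(up_idx, is_tumor.nonzero()[0])] *= fold
    mu[np.ix_(down_idx, is_tumor.nonzero()[0])] /= fold
    for m, l in zip(pair_m, pair_l):
        z = rng.normal(size=n_samp)
        factor = np.exp(cfg.coreg_sigma * z - 0.5 * cfg.coreg_sigma ** 2)
        mu[m] *= factor
        mu[l] *= factor

    # negative-binomial counts (Poisson when dispersion is 0)
    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    counts = pd.DataFrame(counts, index=features, columns=samples)

    # transcripts: one per feature; planted-complementary subset of the
    # co-regulated pairs carries an embedded reverse-complement block
    transcripts = {
        f: {f"{f}.t1": _random_seq(rng, int(rng.integers(60, 121)))} for f in features
    }
    n_comp = int(round(cfg.complementary_fraction * cfg.n_coreg_pairs))
    complementary = []
    for m, l in coreg_pairs[:n_comp]:
        s = transcripts[m][f"{m}.t1"]
        blk = _revcomp(s[:16])
        t = transcripts[l][f"{l}.t1"]
        pos = int(rng.integers(0, max(len(t) - 16, 0) + 1))
        transcripts[l][f"{l}.t1"] = (t[:pos] + blk + t[pos + 16 :])[: len(t)]
        complementary.append((m, l))

    # survival driven by z-scored log2-CPM of the signature lncRNAs;
    # signatures are planted among dysregulated lncRNAs when available so
    # the screening cascade's candidate set can contain them
    if len(de_l_idx) >= cfg.signature_size:
        sig_pos = rng.choice(de_l_idx, size=cfg.signature_size, replace=False)
    else:
        sig_pos = rng.choice(cfg.n_lnc, size=cfg.signature_size, replace=False) + cfg.n_mrna
    signature = list(features[np.asarray(sig_pos, dtype=int)])
    beta = pd.Series(np.asarray(cfg.beta_true, dtype=float), index=signature)
    tumor_cols = list(np.array(samples)[is_tumor])
    tum_counts = counts.loc[:, tumor_cols]
    lib = tum_counts.sum(axis=0).to_numpy()
    logcpm = np.log2((tum_counts.loc[signature].to_numpy() + 0.5) / lib * 1e6)
    if logcpm.size:
        z = (logcpm - logcpm.mean(axis=1, keepdims=True)) / np.maximum(
            logcpm.std(axis=1, keepdims=True), 1e-12
        )
        lp = beta.to_numpy() @ z
    else:
        lp = np.zeros(cfg.n_tumor)
    hazard = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard) if cfg.n_tumor else np.empty(0)
    obs, event = _censor(t_event, cfg.censor_rate, rng) if cfg.n_tumor else (t_event, t_event)
    os_days = np.maximum(np.round(obs), 1.0)

    # clinical covariates; stage correlates with the linear predictor
    age = np.clip(rng.normal(65, 10, size=n_samp), 30, 90).round()
    gender = rng.integers(0, 2, size=n_samp)
    latent = np.zeros(n_samp)
    latent[is_tumor] = cfg.stage_slope * lp + rng.normal(size=cfg.n_tumor)
    cuts = np.quantile(latent[is_tumor], [0.2, 0.5, 0.8]) if cfg.n_tumor else [0, 0, 0]
    stage = np.digitize(latent, cuts) + 1  # 1..4 with probs (.2,.3,.3,.2)
    t_stage = np.clip(stage + rng.integers(-1, 1, size=n_samp), 1, 4)
    n_stage = np.clip(stage - rng.integers(1, 3, size=n_samp), 0, 2)
    m_stage = (stage == 4).astype(int)

    sheet = pd.DataFrame(
        {
            "sample": samples,
            "group": np.where(is_tumor, "tumor", "normal"),
            "age": age.astype(int),
            "gender": gender,
            "stage": stage,
            "T": t_stage,
            "N": n_stage,
            "M": m_stage,
            "os_days": np.nan,
            "event": np.nan,
        }
    ).set_index("sample", drop=False)
    sheet.loc[is_tumor, "os_days"] = os_days
    sheet.loc[is_tumor, "event"] = event.astype(float)
    sheet.loc[~is_tumor, ["stage", "T", "N", "M"]] = 0

    # toy target tables over a shared miRNA pool and a pathogenic list
    mirnas = [f"mir-{i}" for i in range(1, 51)]
    de_lnc = [f for f in de_up + de_down if feature_class[f] == "lncRNA"]
    de_mrna = [f for f in de_up + de_down if feature_class[f] == "mRNA"]
    lnc_pool = sorted(set(de_lnc) | {l for _, l in coreg_pairs})
    mrna_pool = sorted(set(de_mrna) | {m for m, _ in coreg_pairs})
    lnc_rows = [
        (f, mirnas[j]) for f in lnc_pool for j in rng.choice(50, size=3, replace=False)
    ]
    mrna_rows = [
        (f, mirnas[j]) for f in mrna_pool for j in rng.choice(50, size=3, replace=False)
    ]
    lnc_mir = pd.DataFrame(lnc_rows, columns=["feature", "mirna"])
    mrna_mir = pd.DataFrame(mrna_rows, columns=["feature", "mirna"])
    n_path = min(20, len(mrna_pool))
    pathogenic = sorted(rng.choice(mrna_pool, size=n_path, replace=False)) if n_path else []

    truth = {
        "de_up": de_up,
        "de_down": de_down,
        "coreg_pairs": coreg_pairs,
        "complementary_pairs": complementary,
        "signature_lncrnas": signature,
        "beta_true": dict(beta),
        "seed": cfg.seed,
    }
    return SyntheticCohort(
        counts=counts,
        sample_sheet=sheet,
        feature_class=feature_class,
        transcripts=transcripts,
        lnc_mir_targets=lnc_mir,
        mrna_mir_targets=mrna_mir,
        pathogenic_genes=list(pathogenic),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write all cohort artifacts as plain-text files; returns the paths."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "transcripts": out / "transcripts.fasta",
        "lnc_mir": out / "lnc_mir.tsv",
        "mrna_mir": out / "mrna_mir.tsv",
        "pathogenic": out / "pathogenic.txt",
        "truth": out / "truth.json",
    }
    cohort.counts.to_csv(paths["counts"], sep="\t")
    sheet = cohort.sample_sheet.drop(columns="sample")
    sheet.to_csv(paths["samples"], sep="\t")
    with open(paths["transcripts"], "w") as fh:
        for feat, txs in cohort.transcripts.items():
            for tid, seq in txs.items():
                fh.write(f">{feat}|{tid}\n{seq}\n")
    cohort.lnc_mir_targets.to_csv(paths["lnc_mir"], sep="\t", index=False)
    cohort.mrna_mir_targets.to_csv(paths["mrna_mir"], sep="\t", index=False)
    with open(paths["pathogenic"], "w") as fh:
        fh.write("\n".join(cohort.pathogenic_genes) + "\n")
    truth = dict(cohort.truth)
    truth["coreg_pairs"] = [list(p) for p in truth["coreg_pairs"]]
    truth["complementary_pairs"] = [list(p) for p in truth["complementary_pairs"]]
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
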