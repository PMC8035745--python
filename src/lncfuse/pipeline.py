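"""End-to-end orchestration: counts -> DE -> fused correlation -> networks
-> survival screening -> risk model -> validation report.

The pipeline is a deterministic function of its config (all randomness
is seed-controlled) and writes one TSV artifact per stage plus a
key=value run report.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation, fusion, networks, preprocess, structure, survival

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_transcripts"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    counts: str = ""
    samples: str = ""
    transcripts: str = ""  # optional FASTA; empty -> structure stage skipped
    lnc_mir: str = ""
    mrna_mir: str = ""
    pathogenic: str = ""
    outdir: str = "lncfuse_out"
    min_os_days: int = 10
    lfc_thresh: float = 1.5
    p_thresh: float = 0.01
    alpha_coexp: float = 0.8
    alpha_rescue: float = 0.7
    edge_alpha: float = 0.8
    invert_structure_scale: bool = False
    fold_window: int = 300
    screen_p: float = 0.05
    rsf_importance: float = 9.0
    rsf_trees: int = 200
    rsf_repeats: int = 2
    rsf_holdout: float = 0.5
    lasso_cv: int = 10
    drop_p: float = 0.8
    keep_p: float = 0.05
    split_proportion: float = 0.5
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value config file; '#' starts a comment."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str, "bool": lambda v: v.lower() in ("1", "true", "yes")}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            kwargs[key] = casts[types[key]](val)
        return cls(**kwargs)


def read_transcripts(fasta_path) -> dict:
    """FASTA with '<feature>|<transcript>' ids -> {feature: {tid: seq}}."""
    from Bio import SeqIO

    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        feat, _, tid = rec.id.partition("|")
        out.setdefault(feat, {})[tid or rec.id] = str(rec.seq)
    return out


def _stage(report, log, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = _time.perf_counter() - self.t0
            if exc is not None:
                log.append(f"[{name}] FAILED after {elapsed:.1f}s: {exc}")
                report["status"] = "incomplete"
                report["failed_stage"] = name
                raise PipelineError(name, exc) from exc
            log.append(f"[{name}] done in {elapsed:.1f}s")

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk)."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"status": "running", "seed": cfg.seed}
    log: list[str] = []

    with _stage(report, log, "preprocess"):
        counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
        sheet = pd.read_csv(cfg.samples, sep="\t", index_col=0)
        sheet = preprocess.filter_cohort(sheet, cfg.min_os_days)
        counts = counts.loc[:, sheet.index]
        feature_class = pd.Series(
            np.where(counts.index.str.startswith("LNC"), "lncRNA", "mRNA"),
            index=counts.index,
        )
        factors = preprocess.tmm_factors(counts)
        expr = preprocess.log_cpm(counts, factors, feature_class=feature_class)
        de = preprocess.differential_expression(expr, sheet["group"])
        de = preprocess.filter_dysregulated(de, cfg.lfc_thresh, cfg.p_thresh)
        de.to_csv(out / "de.tsv", sep="\t", index=False)
        dys = de[de["direction"] != "ns"]
        de_mrna = dys.index[dys["class"] == "mRNA"].tolist()
        de_lnc = dys.index[dys["class"] == "lncRNA"].tolist()
        report["n_samples"] = int(len(sheet))
        report["n_de_mrna"] = len(de_mrna)
        report["n_de_lncrna"] = len(de_lnc)

    tumor = sheet.index[sheet["group"] == "tumor"]
    with _stage(report, log, "correlation"):
        if not de_mrna or not de_lnc:
            raise ValueError("no dysregulated features in one of the classes")
        c_full = correlation.correlation_block(expr, de_mrna, de_lnc, samples=tumor)
        cml = correlation.threshold_matrix(c_full, cfg.alpha_coexp)
        cml.matrix.to_csv(out / "cml.tsv", sep="\t")
        report["cml_shape"] = f"{cml.matrix.shape[0]}x{cml.matrix.shape[1]}"

    with _stage(report, log, "structure"):
        if cfg.transcripts and not cml.empty:
            transcripts = read_transcripts(cfg.transcripts)
            have = [i for i in cml.row_ids if i in transcripts], [
                j for j in cml.col_ids if j in transcripts
            ]
            model = structure.FoldingModel()
            e = structure.structure_score_matrix(
                transcripts,
                have[0],
                have[1],
                model,
                mfe_fn=lambda a, b: structure.cofold_mfe_windowed(a, b, model, cfg.fold_window),
            )
            e = e.reindex(index=cml.row_ids, columns=cml.col_ids).fillna(0.0)
            eprime = structure.normalize_structure(e, invert=cfg.invert_structure_scale)
            pd.concat(
                {"E": e.stack(), "Eprime": eprime.stack()}, axis=1
            ).rename_axis(["mrna", "lncrna"]).reset_index().to_csv(
                out / "estruct.tsv", sep="\t", index=False
            )
        else:
            eprime = pd.DataFrame(
                0.0, index=cml.row_ids, columns=cml.col_ids
            )  # no sequences: fusion degenerates to C
        report["structure_scored"] = bool(cfg.transcripts) and not cml.empty

    with _stage(report, log, "fusion"):
        ac = fusion.fuse(cml, eprime) if not cml.empty else fusion.AdjustedCorrelation(
            cfg.alpha_coexp, cml.matrix
        )
        ac.matrix.to_csv(out / "ac.tsv", sep="\t")
        if not cml.empty:
            summ = fusion.adjustment_summary(cml, ac)
            report["fusion_total"] = summ.n_total
            report["fusion_unchanged"] = summ.n_unchanged
            report["fusion_adjusted"] = summ.n_adjusted

    with _stage(report, log, "networks"):
        net = networks.coreg_network(ac, cfg.edge_alpha)
        net.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        report["n_coreg_edges"] = net.n_edges
        rescued: list = []
        if cfg.pathogenic:
            pathogenic = [
                line.strip()
                for line in Path(cfg.pathogenic).read_text().splitlines()
                if line.strip()
            ]
            rescue_block = correlation.threshold_matrix(c_full, cfg.alpha_rescue)
            rescue_net = networks.coreg_network(rescue_block.matrix, cfg.alpha_rescue)
            rescued = sorted(networks.rescue_lncrnas(rescue_net, pathogenic))
        report["n_rescued_lncrna"] = len(rescued)
        if cfg.lnc_mir and cfg.mrna_mir:
            cer = networks.cerna_network(
                pd.read_csv(cfg.lnc_mir, sep="\t"),
                pd.read_csv(cfg.mrna_mir, sep="\t"),
                lnc_set=de_lnc,
                mrna_set=de_mrna,
            )
            cer.lnc_edges.to_csv(out / "cerna_lnc.tsv", sep="\t", index=False)
            cer.mrna_edges.to_csv(out / "cerna_mrna.tsv", sep="\t", index=False)
            report["cerna_nodes"] = "{}l/{}m/{}mi".format(*cer.n_nodes)

    with _stage(report, log, "survival"):
        surv_sheet = sheet.loc[tumor]
        surv = survival.SurvivalTable(
            expression=expr.values.loc[de_lnc, tumor].T,
            os_days=surv_sheet["os_days"],
            event=surv_sheet["event"].astype(int),
        )
        cascade = survival.screen_cascade(
            surv,
            de_lnc,
            rescued=rescued,
            p_thresh=cfg.screen_p,
            rsf_importance_thresh=cfg.rsf_importance,
            rsf_trees=cfg.rsf_trees,
            rsf_kwargs={"n_repeats": cfg.rsf_repeats, "holdout": cfg.rsf_holdout},
            lasso_cv=cfg.lasso_cv,
            drop_p=cfg.drop_p,
            keep_p=cfg.keep_p,
            seed=cfg.seed,
        )
        report.update(cascade.counts())
        report["signature"] = ",".join(cascade.signature)
        if cascade.model is not None and cascade.signature:
            cascade.model.signature_summary_.rename_axis("feature").reset_index().to_csv(
                out / "model.tsv", sep="\t", index=False
            )

    with _stage(report, log, "validation"):
        if cascade.model is not None and cascade.signature:
            scores = cascade.model.predict(surv.expression)
            levels = survival.assign_risk(scores)
            train, test = survival.split_cohort(
                surv.expression.index,
                proportion=cfg.split_proportion,
                stratify=surv.event.to_numpy(),
                seed=cfg.seed,
            )
            for name, idx in (("train", train), ("test", test), ("total", surv.expression.index)):
                sub = surv.subset(idx)
                _, stat, p = survival.km_curve(
                    sub.os_days, sub.event, levels.loc[idx]
                )
                report[f"logrank_p_{name}"] = float(p)
            uni, multi = survival.independence_cox(
                (surv.os_days.to_numpy(), surv.event.to_numpy()),
                scores,
                surv_sheet[["age", "gender", "stage", "T", "N", "M"]],
            )
            uni.rename_axis("variable").reset_index().to_csv(
                out / "independence_univariate.tsv", sep="\t", index=False
            )
            multi.rename_axis("variable").reset_index().to_csv(
                out / "independence_multivariate.tsv", sep="\t", index=False
            )
            pd.DataFrame({"risk_score": scores, "risk_level": levels}).rename_axis(
                "sample"
            ).reset_index().to_csv(out / "risk_scores.tsv", sep="\t", index=False)
        else:
            report["logrank_p_total"] = float("nan")

    report["status"] = "complete"
    # config echo so a report fully documents its run
    for f in ("alpha_coexp", "alpha_rescue", "edge_alpha", "lfc_thresh", "p_thresh",
              "screen_p", "rsf_importance", "rsf_trees", "drop_p", "keep_p",
              "split_proportion"):
        report[f"cfg_{f}"] = getattr(cfg, f)
    with open(out / "report.txt", "w") as fh:
        for k, v in report.items():
            fh.write(f"{k}={v}\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    # timings go to a separate log so reports are byte-identical across runs
    (out / "run.log").write_text("\n".join(log) + "\n")
    return report
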