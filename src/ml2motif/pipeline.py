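"""End-to-end pipeline: simulate -> train -> gpoim -> loci -> extract -> eval.

A run is driven by a nested configuration document (YAML or dict) with one
section per stage; unknown keys are rejected so typos fail loudly.  Every
stage writes its artifact plus metadata into the run directory, and a
structured JSON log records the seeds, parameters, and objective traces
actually used.  Reruns with the same config are bit-identical for exact
stages and reproducible (same seed stream) for sampled ones.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .diffpoim import MotifLocus, differential_poim, estimate_motif_loci
from .gpoim import exact_poim, sample_gpoim
from .metrics import classification_accuracy, mrq_aligned
from .motif_extraction import FitConfig, fit_motifs
from .simulate import MotifSpec, generate_dataset
from .scorers import train_wd_svm

_STAGE_KEYS = {
    "simulate": {"n", "L", "motifs", "positive_fraction", "mutation_rate"},
    "train": {"ell_max", "C", "test_fraction", "max_train"},
    "gpoim": {"k", "n", "centered", "exact"},
    "loci": {"k_max", "max_motifs", "exact"},
    "extract": {"k_tilde", "c", "loci", "motifs_per_locus", "tol", "max_iters"},
    "eval": set(),
}


def _parse_motif(entry) -> MotifSpec:
    if isinstance(entry, MotifSpec):
        return entry
    if isinstance(entry, str):  # "SEQ@POS"
        pattern, pos = entry.rsplit("@", 1)
        return MotifSpec(pattern, int(pos))
    return MotifSpec(entry["pattern"], entry["position"], entry.get("name", ""))


class RunConfig:
    """Validated nested stage configuration with a global seed."""

    def __init__(self, doc: dict):
        doc = dict(doc)
        self.seed = int(doc.pop("seed", 0))
        self.outdir = doc.pop("outdir", "run")
        self.stages = {}
        for stage, params in doc.items():
            if stage not in _STAGE_KEYS:
                raise ValueError(f"unknown stage {stage!r}")
            params = dict(params or {})
            unknown = set(params) - _STAGE_KEYS[stage]
            if unknown:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(unknown)}")
            self.stages[stage] = params

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    def require(self, stage: str) -> dict:
        if stage not in self.stages:
            raise ValueError(f"stage not configured: {stage!r}")
        return self.stages[stage]


def run_pipeline(cfg: "RunConfig | dict", outdir=None) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    if not isinstance(cfg, RunConfig):
        cfg = RunConfig(cfg)
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {"seed": cfg.seed, "stages": {}}

    def _record(stage, **info):
        log["stages"][stage] = {"time_s": round(time.time() - t0, 3), **info}
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    t0 = time.time()
    sim = cfg.require("simulate")
    motifs = [_parse_motif(m) for m in sim.get("motifs", [])]
    data = generate_dataset(
        n=sim["n"], L=sim["L"], motifs=motifs,
        positive_fraction=sim.get("positive_fraction", 0.5),
        mutation_rate=sim.get("mutation_rate", 0.0), seed=cfg.seed,
    )
    mio.write_fasta(data, outdir / "dataset.fasta")
    _record("simulate", n=len(data), L=data.L, seed=cfg.seed)

    t0 = time.time()
    tr = cfg.require("train")
    model = train_wd_svm(
        data, ell_max=tr.get("ell_max", 8), C=tr.get("C", 1.0),
        seed=cfg.seed, test_fraction=tr.get("test_fraction", 0.2),
        max_train=tr.get("max_train"),
    )
    model.save(outdir / "model.npz")
    _record("train", **model.meta)

    t0 = time.time()
    gp = cfg.require("gpoim")
    k = gp.get("k", 6)
    if gp.get("exact", False):
        poim = exact_poim(model, k=k, centered=gp.get("centered", True))
    else:
        poim = sample_gpoim(model, k=k, n=gp.get("n", 1000),
                            seed=cfg.seed, centered=gp.get("centered", True))
    mio.write_gpoim_tsv(poim, outdir / "gpoim.tsv")
    _record("gpoim", k=k, n_samples=poim.n_samples, seed=poim.seed)

    loci = None
    if "loci" in cfg.stages:
        t0 = time.time()
        lc = cfg.stages["loci"]
        k_max = lc.get("k_max", min(8, model.ell_max))
        if lc.get("exact", True):
            stack = [exact_poim(model, k=kk) for kk in range(1, k_max + 1)]
        else:
            stack = [
                sample_gpoim(model, k=kk, n=gp.get("n", 1000), seed=cfg.seed + kk)
                for kk in range(1, k_max + 1)
            ]
        dp = differential_poim(stack)
        mio.write_diffpoim_tsv(dp, outdir / "diffpoim.tsv")
        loci = estimate_motif_loci(dp, max_motifs=lc.get("max_motifs", 3))
        (outdir / "loci.json").write_text(json.dumps(
            [{"position": l.position, "length": l.length, "score": l.score}
             for l in loci], indent=2))
        _record("loci", loci=[(l.position, l.length) for l in loci])

    fitted = None
    if "extract" in cfg.stages:
        t0 = time.time()
        ex = cfg.stages["extract"]
        fit_loci = [
            MotifLocus(position=p, length=l, score=0.0)
            for p, l in ex.get("loci", [])
        ] or loci
        if not fit_loci:
            raise ValueError("extract stage needs loci (explicit or from the loci stage)")
        fcfg = FitConfig(
            k_tilde=ex.get("k_tilde", min(6, poim.k)),
            c=ex.get("c", "auto"),
            motifs_per_locus=ex.get("motifs_per_locus", 1),
            tol=ex.get("tol", 1e-10),
            max_iters=ex.get("max_iters", 10000),
        )
        if poim.k != fcfg.k_tilde:
            if gp.get("exact", False):
                fit_poim = exact_poim(model, k=fcfg.k_tilde, centered=poim.centered)
            else:
                fit_poim = sample_gpoim(model, k=fcfg.k_tilde, n=gp.get("n", 1000),
                                        seed=cfg.seed, centered=poim.centered)
        else:
            fit_poim = poim
        fitted = fit_motifs(fit_poim, fit_loci, fcfg)
        for idx, p in enumerate(fitted.ppms, start=1):
            mio.write_pwm(p, outdir / f"motif_{idx}.jaspar", format="jaspar")
            mio.write_pwm(p, outdir / f"motif_{idx}.meme", format="meme")
        (outdir / "fit_report.json").write_text(json.dumps({
            "c_used": fitted.c_used,
            "converged": fitted.converged,
            "iterations": len(fitted.objective_trace) - 1,
            "final_objective": fitted.objective_trace[-1],
            "argmax_sequences": [p.argmax_sequence() for p in fitted.ppms],
        }, indent=2))
        _record("extract", c_used=fitted.c_used,
                iterations=len(fitted.objective_trace) - 1)

    if "eval" in cfg.stages:
        t0 = time.time()
        report = {"test_accuracy": model.meta.get("test_accuracy"),
                  "full_accuracy": classification_accuracy(model, data)}
        if fitted is not None and data.planted:
            mrqs = []
            for p in fitted.ppms:
                best = None
                for m in data.planted:
                    truth = m.pattern if m.is_pwm else _one_hot(m.pattern)
                    score = mrq_aligned(truth, p.r)
                    if best is None or score.value > best.value:
                        best = score
                mrqs.append({"mrq_percent": round(best.percent, 2),
                             "argmax": p.argmax_sequence()})
            report["motifs"] = mrqs
        (outdir / "eval.json").write_text(json.dumps(report, indent=2))
        _record("eval", **{k: v for k, v in report.items() if k != "motifs"})

    return outdir


def _one_hot(pattern: str) -> np.ndarray:
    from ._kmers import seq_to_codes

    codes = seq_to_codes(pattern)
    r = np.zeros((4, len(pattern)))
    r[codes, np.arange(len(pattern))] = 1.0
    return r
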