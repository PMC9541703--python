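"""End-to-end orchestration: simulate/load -> harmonize -> mixture fit ->
conjFDR -> loci -> replication -> enrichment, with a reproducibility manifest.

A pipeline run covers one trait pair.  All stage outputs are tab-delimited
and deterministic for a fixed config (plots exempt); the manifest records
the master seed, a parameter hash and per-stage record counts.  The
transdiagnostic stage is separate (:func:`run_transdiagnostic`) because it
consumes the locus output of two or more pair analyses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causal_mixture import FitConfig, fit_bivariate, fit_univariate
from .cross_trait_fdr import (
    CONJ_FDR_SIGNIFICANCE,
    FDRConfig,
    conditional_qq,
    conjfdr_table,
)
from .locus_definition import (
    LocusConfig,
    annotate_novelty,
    define_loci,
    directional_concordance,
    loci_frame,
    merge_transdiagnostic,
)
from .replication_enrichment import (
    hypergeometric_enrichment,
    map_genes_positional,
    sign_concordance_test,
)
from .sumstats_io import (
    harmonize_pair,
    read_bed,
    read_gmt,
    read_ld_table,
    read_sumstats,
    write_bed,
)
from .synthetic import SimulationConfig, simulate_pair, simulate_replication

__all__ = ["PipelineConfig", "run_pipeline", "run_transdiagnostic"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything one pair analysis needs; see the per-stage config classes."""

    out_dir: str = "crosstrait_out"
    seed: int = 0
    analysis: str = "pair"
    # either a simulation block ...
    simulation: SimulationConfig | None = None
    # ... or paths to real inputs
    sumstats1: str | None = None
    sumstats2: str | None = None
    ld_table: str | None = None
    # stage parameters
    run_mixer: bool = True
    fit: FitConfig = field(default_factory=FitConfig)
    fdr: FDRConfig = field(default_factory=FDRConfig)
    loci: LocusConfig = field(default_factory=LocusConfig)
    replication_n: float | None = None
    known_loci: dict[str, str] = field(default_factory=dict)  # trait -> BED path
    gene_table: str | None = None
    gene_sets: str | None = None
    gene_window: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        for key, sub in (("fit", FitConfig), ("fdr", FDRConfig), ("loci", LocusConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        cfg = cls(**kwargs)
        # derive stage seeds from the master seed
        if cfg.simulation is not None:
            cfg.simulation.seed = cfg.seed
        cfg.fit.seed = cfg.seed
        cfg.fdr.seed = cfg.seed
        return cfg

    def params_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run one pair analysis end to end; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "stages": {},
        "counts": {},
    }

    # --- inputs -----------------------------------------------------------
    truth = ld_for_sim = None
    if config.simulation is not None:
        _, ld, truth, t1, t2, deltas = simulate_pair(config.simulation)
        ld_for_sim = ld
        t1.write(out / "sumstats_trait1.tsv")
        t2.write(out / "sumstats_trait2.tsv")
        _write(truth.df, out / "truth.tsv")
        manifest["stages"]["simulate"] = "ok"
    else:
        for key in ("sumstats1", "sumstats2", "ld_table"):
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"input '{key}' missing or not found: {path}")
        t1 = read_sumstats(config.sumstats1)
        t2 = read_sumstats(config.sumstats2)
        ld = read_ld_table(config.ld_table)
        manifest["stages"]["load"] = "ok"
    manifest["counts"]["variants_trait1"] = len(t1)
    manifest["counts"]["variants_trait2"] = len(t2)

    # --- harmonize --------------------------------------------------------
    pair = harmonize_pair(t1, t2)
    _write(pair.df, out / "merged.tsv")
    manifest["stages"]["harmonize"] = "ok"
    manifest["counts"]["harmonized"] = len(pair)
    manifest["counts"]["ambiguous_dropped"] = pair.n_ambiguous_dropped

    # --- causal mixture ---------------------------------------------------
    if config.run_mixer:
        m = len(pair)
        fit1 = fit_univariate(pair.trait(1), ld, m=m, config=config.fit)
        fit2 = fit_univariate(pair.trait(2), ld, m=m, config=config.fit)
        fitb = fit_bivariate(pair, ld, fit1, fit2, m=m, config=config.fit)
        fitb.iterations.to_csv(out / "mixer_iterations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        summary = {
            **{f"trait1_{k}": v for k, v in fit1.mean.items()},
            **{f"trait2_{k}": v for k, v in fit2.mean.items()},
            **fitb.mean,
            **fitb.derived,
            **{f"aic_{k}": v for k, v in fitb.aic.items()},
        }
        _write(pd.DataFrame([summary]), out / "mixer_summary.tsv")
        manifest["stages"]["mixer"] = "ok"
        manifest["mixer"] = {k: float(v) for k, v in fitb.derived.items()}

    # --- conjFDR ----------------------------------------------------------
    for direction in (1, 2):
        curves = conditional_qq(pair, config.fdr.strata, direction=direction)
        rows = []
        for thr, c in curves.items():
            rows.append(
                pd.DataFrame(
                    {
                        "stratum": thr,
                        "expected": c["expected"],
                        "observed": c["observed"],
                    }
                )
            )
        _write(pd.concat(rows, ignore_index=True), out / f"qq_trait{direction}.tsv")
    table = conjfdr_table(pair, ld, config=config.fdr)
    _write(table, out / "conjfdr.tsv")
    sig = table["conjFDR"] < CONJ_FDR_SIGNIFICANCE
    manifest["stages"]["conjfdr"] = "ok"
    manifest["counts"]["significant_variants"] = int(sig.sum())

    # --- loci -------------------------------------------------------------
    loci = define_loci(table, ld, config.loci, analysis=config.analysis)
    known = {trait: read_bed(path) for trait, path in config.known_loci.items()}
    if known:
        annotate_novelty(loci, known)
    _, k, n, pct = directional_concordance(loci)
    frame = loci_frame(loci)
    _write(frame, out / "loci.tsv")
    pd.DataFrame(
        [
            {
                "lead_snp": L.lead,
                "independent": ",".join(L.independent),
                "candidates": ",".join(L.candidates),
            }
            for L in loci
        ]
    ).to_csv(out / "loci_members.tsv", sep="\t", index=False)
    if len(frame):
        write_bed(
            frame.rename(columns={"start": "START", "end": "END"}), out / "loci.bed"
        )
    manifest["stages"]["loci"] = "ok"
    manifest["counts"]["loci"] = len(loci)
    manifest["concordance"] = {"k": k, "n": n, "percent": pct}

    # --- replication ------------------------------------------------------
    if config.replication_n is not None and truth is not None:
        rep = simulate_replication(
            truth, ld_for_sim, trait=2, n_rep=config.replication_n, seed=config.seed + 1
        )
        rep.write(out / "replication.tsv")
        leads = pd.DataFrame(
            {
                "SNP": [L.lead for L in loci],
                "Z": [L.lead_z2 for L in loci],
            }
        )
        res = sign_concordance_test(leads, rep)
        manifest["stages"]["replication"] = "ok"
        manifest["replication"] = {
            "n": res.n,
            "k": res.k,
            "missing": res.n_missing,
            "p": res.p,
        }

    # --- gene mapping & enrichment ---------------------------------------
    if config.gene_table is not None:
        genes = pd.read_csv(config.gene_table, sep="\t")
        mapped = map_genes_positional(loci, pair.df, genes, window=config.gene_window)
        gene_list = sorted({g for gs in mapped.values() for g in gs})
        pd.DataFrame(
            [(lead, ";".join(gs)) for lead, gs in sorted(mapped.items())],
            columns=["lead_snp", "genes"],
        ).to_csv(out / "mapped_genes.tsv", sep="\t", index=False)
        if config.gene_sets is not None:
            sets = read_gmt(config.gene_sets)
            background = sorted(genes["GENE"].astype(str))
            enr = hypergeometric_enrichment(gene_list, sets, background)
            _write(
                pd.DataFrame([dataclasses.asdict(r) for r in enr]),
                out / "enrichment.tsv",
            )
            manifest["stages"]["enrichment"] = "ok"
        manifest["stages"]["gene_mapping"] = "ok"

    with open(out / "manifest.json", "w") as fh:
        json.dump(_as_jsonable(manifest), fh, indent=2, sort_keys=True)
    return manifest


def _load_analysis(label: str, out_dir: Path | str):
    """Reconstruct (label, loci, conjfdr table) from a pipeline output directory."""
    from .locus_definition import Locus

    out = Path(out_dir)
    table = pd.read_csv(out / "conjfdr.tsv", sep="\t")
    frame = pd.read_csv(out / "loci.tsv", sep="\t")
    members = pd.read_csv(out / "loci_members.tsv", sep="\t").set_index("lead_snp")
    loci = []
    for _, row in frame.iterrows():
        lead = row["lead_snp"]
        loci.append(
            Locus(
                analysis=label,
                chrom=int(row["CHR"]),
                start=int(row["start"]),
                end=int(row["end"]),
                lead=lead,
                independent=str(members.loc[lead, "independent"]).split(","),
                candidates=str(members.loc[lead, "candidates"]).split(","),
                lead_z1=float(row["lead_z1"]),
                lead_z2=float(row["lead_z2"]),
            )
        )
    return label, loci, table


def run_transdiagnostic(
    analyses: list[tuple[str, Path | str]], out_path: Path | str
) -> pd.DataFrame:
    """Merge loci across two or more completed pair analyses.

    ``analyses`` pairs each analysis label with its pipeline output
    directory (needs ``conjfdr.tsv``, ``loci.tsv`` and ``loci_members.tsv``).
    Writes and returns the transdiagnostic locus table.
    """
    loaded = [_load_analysis(label, path) for label, path in analyses]
    trans = merge_transdiagnostic(loaded)
    rows = []
    for T in trans:
        rows.append(
            {
                "CHR": T.chrom,
                "start": T.start,
                "end": T.end,
                "lead_snp": T.lead,
                "analyses": ";".join(T.analyses),
                "conjfdr": ";".join(
                    f"{lab}={T.conjfdr_by_analysis[lab]:.4g}" for lab in T.analyses
                ),
                "concordant": ";".join(
                    f"{lab}={T.concordant_by_analysis.get(lab)}" for lab in T.analyses
                ),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out_path, sep="\t", index=False)
    return frame
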