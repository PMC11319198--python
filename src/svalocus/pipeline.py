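"""Configuration handling and an end-to-end seeded demonstration pipeline.

``run_demo`` chains every stage on synthetic data — simulate reads ->
genotype -> sibling IBD2 concordance -> eQTL/aFC -> splice fractions ->
EHH — and writes a consolidated, byte-reproducible report bundle.  Stage
seeds derive from the master seed by a fixed counter scheme
(``SeedSequence([master_seed, stage_index])``), so any stage can be re-run
in isolation with identical results.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import numbers
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import expression as xp
from . import genotyper as gt
from . import haplotypes as hp
from . import relatedness as rel
from . import splicing as sp
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigValidationError", "StageError", "validate_config", "run_demo"]

# Stage indices for the per-stage seed counter scheme.
STAGE_SEEDS = {"dna": 0, "siblings": 1, "expression": 2, "splice": 3, "haplotypes": 4}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "preset": None,
    "output_dir": "svalocus_demo",
    "locus": {},
    "rules": "ukb",
    "cohort": {"n_samples": 120, "allele_frequency": 0.11},
    "dna": {
        "coverage": 25.0,
        "read_len": 150,
        "frag_mean": 450.0,
        "frag_sd": 100.0,
        "mapq0_prob": 0.8,
    },
    "siblings": {"n_pairs": 30, "n_var": 400, "err_rate": 0.002, "ibd2_fraction": 0.5},
    "expression": {
        "n_samples": 500,
        "beta0": 2.0,
        "afc_true": 2.2,
        "noise_sd_frac": 0.25,
        "n_covariates": 3,
        "n_boot": 1000,
    },
    "splice": {
        "n_samples": 300,
        "p_aberrant_anc": 0.156,
        "p_aberrant_ins": 0.0,
        "allelic_expression_ratio": 2.2,
        "depth": 50.0,
    },
    "haplotypes": {
        "n_hap": 400,
        "n_var": 201,
        "focal_freq": 0.11,
        "sweep_strength": 0.95,
        "mut_rate": 0.001,
    },
}

# (key path, predicate, message) range rules checked during validation
_RANGE_RULES = [
    ("cohort.n_samples", lambda v: v > 0, "must be positive"),
    ("cohort.allele_frequency", lambda v: 0 < v < 1, "must lie in (0, 1)"),
    ("dna.coverage", lambda v: v > 0, "must be positive"),
    ("dna.read_len", lambda v: v > 0, "must be positive"),
    ("dna.frag_mean", lambda v: v > 0, "must be positive"),
    ("dna.frag_sd", lambda v: v > 0, "must be positive"),
    ("dna.mapq0_prob", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    ("siblings.n_pairs", lambda v: v > 0, "must be positive"),
    ("siblings.n_var", lambda v: v > 0, "must be positive"),
    ("siblings.err_rate", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    ("siblings.ibd2_fraction", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    ("expression.n_samples", lambda v: v > 10, "must exceed 10"),
    ("expression.beta0", lambda v: v > 0, "must be positive"),
    ("expression.afc_true", lambda v: v > 0, "must be positive"),
    ("expression.noise_sd_frac", lambda v: v >= 0, "must be non-negative"),
    ("expression.n_covariates", lambda v: v >= 0, "must be non-negative"),
    ("expression.n_boot", lambda v: v >= 1000, "must be at least 1000"),
    ("splice.n_samples", lambda v: v > 0, "must be positive"),
    ("splice.p_aberrant_anc", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    ("splice.p_aberrant_ins", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    ("splice.allelic_expression_ratio", lambda v: v > 0, "must be positive"),
    ("splice.depth", lambda v: v > 0, "must be positive"),
    ("haplotypes.n_hap", lambda v: v >= 4, "must be at least 4"),
    ("haplotypes.n_var", lambda v: v >= 3, "must be at least 3"),
    ("haplotypes.focal_freq", lambda v: 0 < v < 1, "must lie in (0, 1)"),
    ("haplotypes.sweep_strength", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
    ("haplotypes.mut_rate", lambda v: 0 <= v <= 1, "must lie in [0, 1]"),
]


@dataclass(frozen=True)
class PipelineConfig:
    """Fully-defaulted, validated pipeline configuration."""

    values: dict

    def __getitem__(self, key: str):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, STAGE_SEEDS[stage]]))

    def sha256(self) -> str:
        # the output location is not a parameter of the computation
        values = {k: v for k, v in self.values.items() if k != "output_dir"}
        blob = json.dumps(values, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class ConfigValidationError(ValueError):
    """Carries the complete list of configuration violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _lookup(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        node = node[part]
    return node


def _merge(base: dict, override: dict, prefix: str, errors: list[str]) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            errors.append(f"unknown config key: {path}")
            continue
        if isinstance(base[key], dict) and key != "locus":
            if not isinstance(value, dict):
                errors.append(f"{path} must be a mapping")
                continue
            out[key] = _merge(base[key], value, f"{path}.", errors)
        else:
            out[key] = value
    return out


def validate_config(source) -> PipelineConfig:
    """Validate a config file/mapping, returning the fully-defaulted config.

    All violations (unknown keys, out-of-range values) are collected and
    raised together as :class:`ConfigValidationError`; an empty file yields
    the all-defaults configuration.  A ``preset`` name layers the packaged
    preset between the defaults and the user's own overrides.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    if not isinstance(user, dict):
        raise ConfigValidationError(["config root must be a mapping"])

    errors: list[str] = []
    base = copy.deepcopy(DEFAULT_CONFIG)
    preset_name = user.get("preset", None)
    if preset_name is not None:
        try:
            preset = syn.load_preset(str(preset_name))
        except ValueError as exc:
            raise ConfigValidationError([str(exc)]) from None
        for block in ("cohort", "dna", "splice", "expression"):
            if block in preset:
                base[block] = _merge(base[block], preset[block], f"{block}.", errors)
        if "rules" in preset:
            base["rules"] = preset["rules"]
    merged = _merge(base, user, "", errors)

    if not isinstance(merged["seed"], numbers.Integral):
        errors.append("seed must be an integer")
    if str(merged["rules"]).lower() not in ("kgp", "ukb", "gtex"):
        errors.append("rules must be one of kgp, ukb, gtex")
    for dotted, pred, msg in _RANGE_RULES:
        try:
            value = _lookup(merged, dotted)
        except KeyError:
            continue
        if not isinstance(value, numbers.Number) or isinstance(value, bool):
            errors.append(f"{dotted} must be numeric")
        elif not pred(value):
            errors.append(f"{dotted} {msg}")
    if merged["locus"]:
        try:
            syn.build_locus_model(merged["locus"])
        except (syn.LocusConfigError, TypeError) as exc:
            errors.append(f"locus: {exc}")
    if errors:
        raise ConfigValidationError(sorted(errors))
    return PipelineConfig(values=merged)


def _provenance(config: PipelineConfig) -> str:
    return f"# svalocus {__version__} | seed={config.seed} | config={config.sha256()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_demo(config: PipelineConfig, output_dir=None) -> dict:
    """Run every stage on synthetic data and write the report bundle.

    Returns a summary dict (also written as ``report.json``).  Identical
    config + seed produce byte-identical outputs.  A failure in any stage
    raises :class:`StageError` naming the stage.
    """
    out = Path(output_dir if output_dir is not None else config["output_dir"])
    model = syn.build_locus_model(config["locus"])
    locus = syn.locus_spec_from_model(model)
    rules = gt.RuleSet.by_name(config["rules"])
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool": f"svalocus {__version__}",
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "rule_set": rules.name,
    }
    dna_cfg = config["dna"]

    def genotype_sample(sample_id: str, dosage: int, rng) -> gt.InsertionEvidence:
        truth = syn.SimTruth(sample_id=sample_id, genotype_dosage=int(dosage))
        reads = syn.simulate_dna_read_pairs(
            truth,
            model,
            coverage=dna_cfg["coverage"],
            read_len=int(dna_cfg["read_len"]),
            frag_mean=dna_cfg["frag_mean"],
            frag_sd=dna_cfg["frag_sd"],
            mapq0_prob=dna_cfg["mapq0_prob"],
            seed=rng,
        )
        return gt.count_evidence(reads, locus, rules, sample_id)

    # --- stage 1: simulate DNA evidence and genotype the cohort -----------
    try:
        rng = config.stage_rng("dna")
        n = int(config["cohort"]["n_samples"])
        dosages = syn.simulate_dosages(n, config["cohort"]["allele_frequency"], rng)
        evidence = [genotype_sample(f"S{k:05d}", dosages[k], rng) for k in range(n)]
        calls = gt.calls_from_evidence(evidence, rules)
        calls["true_dosage"] = dosages
        _write_tsv(calls, out / "evidence.tsv", config)
        gt.write_genotype_vcf(calls, locus, out / "genotypes.vcf", model.contig_length)
        called = calls.dropna(subset=["dosage"])
        _, r2 = rel.genotype_concordance(
            called["true_dosage"].to_numpy(float), called["dosage"].to_numpy(float)
        )
        summary["genotyping"] = {
            "n_samples": n,
            "call_counts": calls["call"].value_counts().to_dict(),
            "dosage_r2_vs_truth": round(float(r2), 6),
        }
        logger.info("genotyping stage: n=%d r2=%.4f", n, r2)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("genotype", exc) from exc

    # --- stage 2: sibling IBD2 flagging and call concordance --------------
    try:
        rng = config.stage_rng("siblings")
        sib_cfg = config["siblings"]
        sib = syn.simulate_sibling_genotypes(
            int(sib_cfg["n_pairs"]), int(sib_cfg["n_var"]),
            sib_cfg["err_rate"], sib_cfg["ibd2_fraction"], seed=rng,
        )
        results = rel.flag_ibd2_pairs(sib.geno_a, sib.geno_b, sib.positions, sib.center, sib.window)
        # SVA genotype calls for each sibling: IBD2 pairs share the true dosage
        af = config["cohort"]["allele_frequency"]
        dos_a = syn.simulate_dosages(len(results), af, rng)
        dos_b = np.where(
            sib.ibd2, dos_a, syn.simulate_dosages(len(results), af, rng)
        )
        call_a, call_b = [], []
        for k, res in enumerate(results):
            ev_a = genotype_sample(f"SIBA{k:04d}", dos_a[k], rng)
            ev_b = genotype_sample(f"SIBB{k:04d}", dos_b[k], rng)
            call_a.append(gt.call_genotype(ev_a, rules))
            call_b.append(gt.call_genotype(ev_b, rules))
        results = [
            rel.SibPairResult(r.pair_id, r.n_mismatch, r.ibd2, ca.call.value, cb.call.value)
            for r, ca, cb in zip(results, call_a, call_b)
        ]
        table = rel.pair_table(results)
        _write_tsv(table, out / "sibling_pairs.tsv", config)
        flagged = [k for k, r in enumerate(results) if r.ibd2]
        da = np.array([call_a[k].dosage for k in flagged], dtype=float)
        db = np.array([call_b[k].dosage for k in flagged], dtype=float)
        frac, r2 = rel.genotype_concordance(da, db)
        summary["siblings"] = {
            "n_pairs": len(results),
            "n_ibd2_flagged": len(flagged),
            "fraction_concordant": round(frac, 6),
            "dosage_r2": None if np.isnan(r2) else round(float(r2), 6),
        }
    except Exception as exc:
        raise StageError("concordance", exc) from exc

    # --- stage 3: expression eQTL and allelic fold change ------------------
    try:
        rng = config.stage_rng("expression")
        ex = config["expression"]
        n = int(ex["n_samples"])
        dosages = syn.simulate_dosages(n, config["cohort"]["allele_frequency"], rng)
        truths = [syn.SimTruth(f"E{k:05d}", int(d)) for k, d in enumerate(dosages)]
        k_cov = int(ex["n_covariates"])
        covariates = rng.normal(0.0, 1.0, (n, k_cov)) if k_cov else None
        effects = (0.5 * 0.5 ** np.arange(k_cov)) if k_cov else None
        y = syn.simulate_expression(
            truths, ex["beta0"], ex["afc_true"], covariates, effects,
            noise_sd=ex["noise_sd_frac"] * ex["beta0"], seed=rng,
        )
        fit = xp.fit_eqtl_linear(y, dosages.astype(float), covariates)
        est = xp.afc_with_ci(
            y, dosages.astype(float), covariates,
            n_boot=int(ex["n_boot"]), seed=config.seed + 1,
        )
        afc_df = pd.DataFrame(
            [
                {
                    "beta0": fit.beta0,
                    "beta_g": fit.beta_g,
                    "afc": est.afc,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_boot": est.n_boot,
                    "n": fit.n,
                    "afc_true": ex["afc_true"],
                }
            ]
        )
        _write_tsv(afc_df, out / "afc.tsv", config)
        summary["expression"] = {
            "afc": round(est.afc, 4),
            "ci": [round(est.ci_low, 4), round(est.ci_high, 4)],
            "afc_true": ex["afc_true"],
        }
    except Exception as exc:
        raise StageError("eqtl", exc) from exc

    # --- stage 4: splice-junction fractions by genotype ---------------------
    try:
        rng = config.stage_rng("splice")
        spl = config["splice"]
        cfg = syn.SpliceSimConfig(
            p_aberrant_anc=spl["p_aberrant_anc"],
            p_aberrant_ins=spl["p_aberrant_ins"],
            allelic_expression_ratio=spl["allelic_expression_ratio"],
            depth=spl["depth"],
        )
        n = int(spl["n_samples"])
        dosages = syn.simulate_dosages(n, config["cohort"]["allele_frequency"], rng)
        rows = []
        by_geno: dict[int, list[tuple[int, int]]] = {0: [], 1: [], 2: []}
        for k, d in enumerate(dosages):
            truth = syn.SimTruth(f"Q{k:05d}", int(d))
            n_can, n_ab = syn.simulate_splice_counts(truth, cfg, seed=rng)
            by_geno[int(d)].append((n_ab, n_can))
            rows.append({"sample_id": truth.sample_id, "dosage": int(d),
                         "n_aberrant": n_ab, "n_canonical": n_can})
        _write_tsv(pd.DataFrame(rows), out / "splice_counts.tsv", config)
        combined = {}
        for d, counts in by_geno.items():
            if counts:
                sf = sp.combined_splice_fraction(counts)
                combined[d] = None if sf.fraction is None else round(sf.fraction, 6)
        summary["splicing"] = {
            "combined_fraction_by_dosage": combined,
            "expected_fraction_by_dosage": {
                d: round(cfg.expected_fraction(d), 6) for d in (0, 1, 2)
            },
        }
    except Exception as exc:
        raise StageError("sqtl", exc) from exc

    # --- stage 5: extended haplotype homozygosity ---------------------------
    try:
        rng = config.stage_rng("haplotypes")
        hcfg = config["haplotypes"]
        panel = syn.simulate_haplotype_panel(
            int(hcfg["n_hap"]), int(hcfg["n_var"]), hcfg["focal_freq"],
            hcfg["sweep_strength"], hcfg["mut_rate"], seed=rng,
        )
        curves = [hp.ehh_curve(panel, allele) for allele in (1, 0)]
        _write_tsv(hp.curve_table(curves, panel), out / "ehh.tsv", config)
        half_idx = panel.focal_index // 2  # quarter-panel distance from focal
        summary["haplotypes"] = {
            "ehh_derived_at_quarter": round(curves[0].value_at(half_idx), 6)
            if half_idx in curves[0].variant_indices else 0.0,
            "ehh_ancestral_at_quarter": round(curves[1].value_at(half_idx), 6)
            if half_idx in curves[1].variant_indices else 0.0,
        }
    except Exception as exc:
        raise StageError("ehh", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
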