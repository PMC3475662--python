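"""End-to-end orchestration: simulate -> estimate -> call -> classify ->
partition -> kinetics, with a reproducible manifest.

The demo configuration emulates a two-strain comparison: a construct
carrying an active conditional fork barrier next to the marker and a
barrier-free control.  Every stage draws from named child streams of a
single master seed, so a re-run with the same configuration reproduces
byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .event_calls import EventClass, classify_colony
from .fluctuation import (
    Condition,
    aggregate_rates,
    estimate_rate_median,
    rank_sum_test,
)
from .kinetics import slippage_rate_per_generation
from .rate_partition import partition_strain
from .seq_classify import classify_mutation, spectrum_table
from .synthetic import SimConfig, rng_for, simulate_colony_population, simulate_kinetics, simulate_fluctuation

__all__ = ["PipelineError", "default_run_config", "run_all"]

logger = logging.getLogger("forkslip")

REPORT_FILES = ("table1.tsv", "table2.tsv", "slopes.tsv", "summary.txt")


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""


def default_run_config() -> dict:
    """Demo configuration: one barrier strain and one barrier-free
    control, three replicate fluctuation experiments each, 200 colonies
    genotyped per strain and condition, and reversion kinetics for a
    duplication-allele strain with and without the barrier."""
    return {
        "seed": 0,
        "control": "t-ura4-ori",
        "n_replicates": 3,
        "n_colonies": 200,
        "strains": {
            "t-ura4-ori": {"mu_off": 4.6e-8, "mu_on": 4.3e-8},
            "t-ura4<ori": {"mu_off": 4.1e-8, "mu_on": 13.9e-8},
        },
        "kinetics": {
            "t-ura4-dup20-ori": 5e-8,
            "t-ura4-dup20<ori": 5e-7,
        },
        "sim": {},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _estimate_strain(cfg: SimConfig, strain: str, n_replicates: int) -> dict:
    out: dict = {}
    for condition in (Condition.RFB_OFF, Condition.RFB_ON):
        rates = []
        for rep in range(n_replicates):
            rng = rng_for(cfg.seed, f"fluct/{strain}/{condition.value}/{rep}")
            cultures = simulate_fluctuation(cfg, condition, rng=rng)
            est = estimate_rate_median(cultures, seed=cfg.seed + rep)
            rates.append(est.rate)
        out[condition] = {"rates": rates, "summary": aggregate_rates(rates)}
    _, p = rank_sum_test(out[Condition.RFB_ON]["rates"], out[Condition.RFB_OFF]["rates"])
    out["p_on_vs_off"] = p
    return out


def _genotype_strain(cfg: SimConfig, strain: str, n_colonies: int) -> dict:
    out = {}
    ref_rng = rng_for(cfg.seed, "reference")
    for condition in (Condition.RFB_OFF, Condition.RFB_ON):
        rng = rng_for(cfg.seed, f"colonies/{strain}/{condition.value}")
        assays, _ = simulate_colony_population(cfg, n_colonies, condition, rng=rng)
        calls = {a.colony_id: classify_colony(a) for a in assays}
        valid = [a for a in assays if calls[a.colony_id] is not EventClass.INVALID]
        n = len(valid)
        counts = {
            "deletion": sum(
                calls[a.colony_id] is EventClass.DELETION for a in valid
            ),
            "translocation": sum(
                calls[a.colony_id] is EventClass.TRANSLOCATION for a in valid
            ),
        }
        counts["mutation"] = n - counts["deletion"] - counts["translocation"]
        from .synthetic import generate_reference

        ref = generate_reference(cfg, rng_for(cfg.seed, "reference"))
        records = [
            classify_mutation(ref, a.ura4_sequence)
            for a in valid
            if calls[a.colony_id] is EventClass.POINT_MUTATION_CANDIDATE
            and a.ura4_sequence
        ]
        out[condition] = {
            "fractions": {k: v / n for k, v in counts.items()},
            "spectrum": spectrum_table(records, strain, condition.value),
        }
    return out


def run_all(config: Optional[dict] = None, outdir="forkslip_run", seed: Optional[int] = None) -> dict:
    """Run the full synthetic study and write report tables.

    Emits ``table1.tsv`` (per-strain OFF/ON rates, fold induction by
    barrier expression, rank-sum p, fold versus the control construct),
    ``table2.tsv`` (mutation spectra with balanced per-category rates),
    ``slopes.tsv`` (per-strain slippage rate per generation), a plain
    text summary and a JSON run manifest.  Returns the path map.
    """
    config = {**default_run_config(), **(config or {})}
    if seed is not None:
        config["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    logging.basicConfig(stream=sys.stderr, format="%(name)s: %(message)s")

    control = config["control"]
    if control not in config["strains"]:
        raise PipelineError(
            f"config: control strain {control!r} is required by fold_vs_control "
            "but missing from 'strains'"
        )

    try:
        # -- stage: estimate -------------------------------------------------
        logger.info("[estimate] fluctuation experiments")
        estimates = {}
        for strain, params in config["strains"].items():
            cfg = SimConfig(seed=config["seed"], **{**config.get("sim", {}), **params})
            estimates[strain] = _estimate_strain(cfg, strain, config["n_replicates"])

        # -- stage: call + classify ------------------------------------------
        logger.info("[classify] colony genotyping and mutation spectra")
        genotypes = {}
        for strain, params in config["strains"].items():
            cfg = SimConfig(seed=config["seed"], **{**config.get("sim", {}), **params})
            genotypes[strain] = _genotype_strain(cfg, strain, config["n_colonies"])

        # -- stage: partition -------------------------------------------------
        logger.info("[partition] balanced and induced rates")
        control_rate_on = estimates[control][Condition.RFB_ON]["summary"].mean_rate
        table1_rows = []
        table2_rows = []
        partitions = {}
        for strain in config["strains"]:
            est = estimates[strain]
            rate_on = est[Condition.RFB_ON]["summary"].mean_rate
            rate_off = est[Condition.RFB_OFF]["summary"].mean_rate
            part = partition_strain(
                strain,
                rate_on,
                rate_off,
                genotypes[strain][Condition.RFB_ON]["fractions"],
                genotypes[strain][Condition.RFB_OFF]["fractions"],
                control_rate_on=None if strain == control else control_rate_on,
            )
            partitions[strain] = part
            table1_rows.append(
                {
                    "strain": strain,
                    "rate_off": rate_off,
                    "rate_on": rate_on,
                    "fold_rtf1": round(part.fold_rtf1, 1),
                    "p_value": est["p_on_vs_off"],
                    "fold_vs_control": (
                        "" if strain == control else round(part.fold_vs_control, 1)
                    ),
                }
            )
            for condition in (Condition.RFB_OFF, Condition.RFB_ON):
                spec = genotypes[strain][condition]["spectrum"]
                mutation_rate = (
                    part.class_rates_on if condition is Condition.RFB_ON
                    else part.class_rates_off
                ).get("mutation", 0.0)
                total = spec.total
                for cat, count in sorted(spec.counts.items()):
                    table2_rows.append(
                        {
                            "strain": strain,
                            "condition": condition.value,
                            "category": cat,
                            "count": count,
                            "rate": mutation_rate * count / total if total else 0.0,
                        }
                    )

        # -- stage: kinetics ---------------------------------------------------
        logger.info("[kinetics] slippage rate per generation")
        slope_rows = []
        for strain, rate in config.get("kinetics", {}).items():
            cfg = SimConfig(
                seed=config["seed"], **{**config.get("sim", {}), "kinetics_rate": rate}
            )
            series = simulate_kinetics(
                cfg, rng=rng_for(cfg.seed, f"kinetics/{strain}"), strain_id=strain
            )
            slip = slippage_rate_per_generation(series)
            slope_rows.append(
                {
                    "strain": strain,
                    "slippage_rate_per_generation": slip.rate,
                    "se": slip.se,
                    "n_experiments": series.n_experiments,
                }
            )

        # -- stage: report ------------------------------------------------------
        logger.info("[report] writing tables")
        table1 = outdir / "table1.tsv"
        pd.DataFrame(table1_rows).to_csv(table1, sep="\t", index=False)
        written.append(table1)
        table2 = outdir / "table2.tsv"
        pd.DataFrame(table2_rows).to_csv(table2, sep="\t", index=False)
        written.append(table2)
        slopes = outdir / "slopes.tsv"
        pd.DataFrame(slope_rows).to_csv(slopes, sep="\t", index=False)
        written.append(slopes)

        summary = outdir / "summary.txt"
        lines = [f"forkslip {__version__} synthetic study (seed={config['seed']})", ""]
        for row in table1_rows:
            lines.append(
                f"{row['strain']}: rate OFF {row['rate_off']:.3g}, "
                f"ON {row['rate_on']:.3g} events/cell/division, "
                f"fold induction {row['fold_rtf1']} (p={row['p_value']:.3g})"
            )
        for row in slope_rows:
            lines.append(
                f"{row['strain']}: slippage rate "
                f"{row['slippage_rate_per_generation']:.3g}/generation "
                f"(SE {row['se']:.2g})"
            )
        summary.write_text("\n".join(lines) + "\n")
        written.append(summary)

        manifest = {
            "tool": "forkslip",
            "version": __version__,
            "seed": config["seed"],
            "config": {
                k: v for k, v in config.items() if k != "seed"
            },
            "outputs": {p.name: _sha256(p) for p in written},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc

    return {p.name: p for p in written + [manifest_path]}
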