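"""TSV and FASTA readers/writers for the pipeline's file dialects.

All tables are UTF-8, tab-separated, '.' decimal separator, with a
header row.  Sequences travel as single- or multi-record FASTA whose
description line carries the colony identifier.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .event_calls import ColonyAssay
from .fluctuation import Condition, Culture, CultureSet
from .kinetics import KineticsSeries
from .seq_classify import MutationRecord
from .synthetic import TruthRecord

__all__ = [
    "read_cultures_tsv",
    "write_cultures_tsv",
    "read_assays_tsv",
    "write_assays_tsv",
    "read_series_tsv",
    "write_series_tsv",
    "read_fasta",
    "write_fasta",
    "write_records_tsv",
    "write_truth_tsv",
]


def read_cultures_tsv(path) -> list[CultureSet]:
    """One CultureSet per (strain_id, condition) group of the table."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "condition", "n_viable", "n_selected", "plating_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sets = []
    for (strain, cond), grp in df.groupby(["strain_id", "condition"], sort=False):
        pf = grp["plating_fraction"].unique()
        if len(pf) != 1:
            raise ValueError(
                f"{path}: plating_fraction must be constant within "
                f"({strain}, {cond})"
            )
        sets.append(
            CultureSet(
                strain_id=str(strain),
                condition=Condition(str(cond)),
                cultures=[
                    Culture(float(v), float(s))
                    for v, s in zip(grp["n_viable"], grp["n_selected"])
                ],
                plating_fraction=float(pf[0]),
            )
        )
    return sets


def write_cultures_tsv(path, culture_sets: Iterable[CultureSet]) -> None:
    rows = [
        {
            "strain_id": cs.strain_id,
            "condition": cs.condition.value,
            "n_viable": c.n_viable,
            "n_selected": c.n_selected,
            "plating_fraction": cs.plating_fraction,
        }
        for cs in culture_sets
        for c in cs.cultures
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assays_tsv(path, sequences: Optional[dict] = None) -> list[ColonyAssay]:
    df = pd.read_csv(path, sep="\t")
    sequences = sequences or {}
    return [
        ColonyAssay(
            colony_id=str(r.colony_id),
            ura4_amplified=bool(r.ura4_amplified),
            rng3_amplified=bool(r.rng3_amplified),
            tl_junction_amplified=bool(r.tl_amplified),
            ura4_sequence=sequences.get(str(r.colony_id)),
        )
        for r in df.itertuples()
    ]


def write_assays_tsv(path, assays: Iterable[ColonyAssay]) -> None:
    rows = [
        {
            "colony_id": a.colony_id,
            "ura4_amplified": int(a.ura4_amplified),
            "rng3_amplified": int(a.rng3_amplified),
            "tl_amplified": int(a.tl_junction_amplified),
        }
        for a in assays
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_series_tsv(path) -> list[KineticsSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for strain, grp in df.groupby("strain_id", sort=False):
        experiments = [
            exp[["generations", "frequency"]].to_numpy(dtype=float)
            for _, exp in grp.groupby("experiment_id", sort=False)
        ]
        out.append(KineticsSeries(strain_id=str(strain), experiments=experiments))
    return out


def write_series_tsv(path, series_list: Iterable[KineticsSeries]) -> None:
    rows = [
        {
            "strain_id": s.strain_id,
            "experiment_id": i,
            "generations": g,
            "frequency": f,
        }
        for s in series_list
        for i, exp in enumerate(s.experiments)
        for g, f in exp
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Map record id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_records_tsv(path, records: Iterable[tuple[str, MutationRecord]]) -> None:
    """One row per classified mutation, keyed by colony id."""
    rows = [
        {
            "colony_id": cid,
            "kind": r.kind.value,
            "pos": r.pos,
            "ref_seg": r.ref_seg,
            "alt_seg": r.alt_seg,
            "size": r.size,
            "mh_len": r.mh_len,
            "placement_start": r.placement_range[0],
            "placement_end": r.placement_range[1],
            "context": r.context.value,
            "sub_class": r.sub_class,
        }
        for cid, r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_tsv(path, truths: Iterable[TruthRecord]) -> None:
    rows = [
        {
            "colony_id": t.colony_id,
            "true_class": t.true_class,
            "true_kind": t.true_kind,
            "true_pos": t.true_pos,
            "true_size": t.true_size,
            "true_mh": t.true_mh,
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
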