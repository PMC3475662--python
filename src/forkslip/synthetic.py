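"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes: Luria-Delbrueck fluctuation
cultures, an ORF-scale reference sequence with planted direct-repeat
pairs, mutant alleles with planted events from the mutation taxonomy,
colony PCR assay populations, and linear revertant-frequency kinetics.
All outputs are deterministic functions of a single integer master seed;
per-stage generators are derived from named child streams so each stage
is independently reproducible.

The growth model is synchronous binary fission: at each generation every
wild-type cell divides and, with probability mu (the mutation rate per
cell per division), the division produces one mutant daughter whose
clone then breeds true, grows at the same rate, never reverts and never
dies.  These are exactly the assumptions of the method-of-the-median
estimator, with the expected number of mutation events per culture
m = mu * (Nt - n0) ~= mu * Nt.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .event_calls import ColonyAssay
from .fluctuation import Condition, Culture, CultureSet
from .kinetics import KineticsSeries
from .seq_classify import classify_mutation

__all__ = [
    "SimConfig",
    "RepeatSpec",
    "EventSpec",
    "TruthRecord",
    "SimulationError",
    "rng_for",
    "simulate_fluctuation",
    "generate_reference",
    "find_repeat_pairs",
    "plant_event",
    "simulate_colony_population",
    "simulate_kinetics",
]

_BASES = np.array(list("ACGT"))
#: Desk-scale cap on the final population size of a simulated culture.
MAX_POPULATION = 10**9
#: Shortest spurious exact repeat rejected in generated references.
SPURIOUS_REPEAT_LEN = 12


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatSpec:
    """One planted direct-repeat pair: motif length and start-to-start
    spacing (= the size of the slippage event it mediates)."""

    motif_len: int
    spacing: int

    def __post_init__(self) -> None:
        if not 1 <= self.motif_len <= 10:
            raise SimulationError("motif_len must be in 1..10")
        if not 2 <= self.spacing <= 50:
            raise SimulationError("spacing must be in 2..50")
        if self.spacing <= self.motif_len:
            raise SimulationError("spacing must exceed motif_len (non-overlapping)")


#: Direct-repeat plan of the default reference: motif lengths span the
#: observed 1-10 nt micro-homology range and spacings give a median
#: slippage size of ~23 nt.
DEFAULT_REPEAT_PLAN = (
    RepeatSpec(5, 20),
    RepeatSpec(4, 22),
    RepeatSpec(3, 24),
    RepeatSpec(6, 18),
    RepeatSpec(2, 12),
    RepeatSpec(7, 30),
    RepeatSpec(8, 26),
    RepeatSpec(1, 8),
    RepeatSpec(10, 50),
    RepeatSpec(9, 40),
)

#: Event mixture over colony classes: fractions of genomic deletion,
#: translocation and sequence-level mutation among selected colonies.
DEFAULT_CLASS_MIXTURE = {"deletion": 0.55, "translocation": 0.05, "mutation": 0.40}

#: Mutation-spectrum mixture (conditional on a mutation colony),
#: proportional to the event counts observed for the single-barrier
#: construct under fork arrest: 52 substitutions, 8 frameshifts, 27
#: deletions and 12 duplications among 99 events.
DEFAULT_MUTATION_SPECTRUM = {
    "GC->AT": 14 / 99,
    "AT->GC": 9 / 99,
    "GC->TA": 20 / 99,
    "GC->CG": 3 / 99,
    "AT->CG": 4 / 99,
    "AT->TA": 2 / 99,
    "fs_plus_mono": 1 / 99,
    "fs_minus_homo": 4 / 99,
    "fs_minus_mono": 3 / 99,
    "deletions": 27 / 99,
    "duplications": 12 / 99,
}


@dataclass
class SimConfig:
    """Full generative specification for one synthetic study.

    Rates are events/cell/division.  The defaults emulate the
    single-barrier construct: a spontaneous loss rate of 4e-8 rising to
    1.4e-7 under fork arrest, cultures grown from 100 cells for 20
    generations (final count ~1e8, chosen so the expected number of
    mutation events per culture, m = mu*Nt ~ 4-15, sits in the range
    where the method of the median is accurate), at least 11 cultures
    per experiment, and a revertant frequency growing by 5e-7 per
    generation.
    """

    seed: int = 0
    mu_off: float = 4e-8
    mu_on: float = 1.4e-7
    n0: int = 100
    generations: int = 20
    n_cultures: int = 11
    plating_fraction: float = 1.0
    event_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    mutation_spectrum: dict = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_SPECTRUM)
    )
    ref_length: int = 795
    repeat_plan: tuple = DEFAULT_REPEAT_PLAN
    kinetics_rate: float = 5e-7
    kinetics_baseline: float = 2e-7
    noise_sd: float = 0.1
    n_experiments: int = 3

    def __post_init__(self) -> None:
        for name, mix in (("event_mixture", self.event_mixture),
                          ("mutation_spectrum", self.mutation_spectrum)):
            if any(v < 0 for v in mix.values()):
                raise SimulationError(f"{name}: proportions must be >= 0")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise SimulationError(f"{name}: proportions must sum to 1")
        if not 0 < self.plating_fraction <= 1:
            raise SimulationError("plating_fraction must be in (0, 1]")
        self.repeat_plan = tuple(
            r if isinstance(r, RepeatSpec) else RepeatSpec(*r) for r in self.repeat_plan
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic colony."""

    colony_id: str
    true_class: str
    true_kind: str = ""
    true_pos: int = 0
    true_size: int = 0
    true_mh: int = 0


@dataclass(frozen=True)
class EventSpec:
    """Requested planted event.

    ``kind`` is a mutation-spectrum category key (a substitution class,
    ``fs_plus_homo``/``fs_plus_mono``/``fs_minus_homo``/``fs_minus_mono``,
    ``deletions`` or ``duplications``).  For slippage events ``size``
    optionally pins the repeat spacing to use.
    """

    kind: str
    size: Optional[int] = None


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named child generator derived deterministically from the master
    seed, so every stage is independently reproducible."""
    digest = hashlib.sha256(stream.encode()).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), child]))


# ---------------------------------------------------------------------------
# Fluctuation cultures


def simulate_fluctuation(
    cfg: SimConfig,
    condition: Condition,
    rng: Optional[np.random.Generator] = None,
) -> CultureSet:
    """Simulate one fluctuation experiment under the Luria-Delbrueck model.

    Synchronous generations: each wild-type division yields one mutant
    daughter with probability mu, so mutants arising early form jackpot
    clones.  Counts are reported as plated (a binomial thinning by the
    plating fraction when it is below one).
    """
    condition = Condition(condition)
    if cfg.n0 * 2**cfg.generations > MAX_POPULATION:
        raise SimulationError(
            f"n0 * 2^generations exceeds the population guard of {MAX_POPULATION:.0e}; "
            "reduce generations or n0"
        )
    if rng is None:
        rng = rng_for(cfg.seed, f"fluctuation/{condition.value}")
    mu = cfg.mu_on if condition is Condition.RFB_ON else cfg.mu_off

    n_wild = np.full(cfg.n_cultures, cfg.n0, dtype=np.int64)
    n_mut = np.zeros(cfg.n_cultures, dtype=np.int64)
    for _ in range(cfg.generations):
        new_mut = rng.binomial(n_wild, mu)
        n_wild = 2 * n_wild - new_mut
        n_mut = 2 * n_mut + new_mut
    n_total = n_wild + n_mut

    if cfg.plating_fraction < 1.0:
        viable = rng.binomial(n_total, cfg.plating_fraction)
        selected = np.minimum(rng.binomial(n_mut, cfg.plating_fraction), viable)
        viable = np.maximum(viable, 1)
    else:
        viable, selected = n_total, n_mut

    cultures = [Culture(int(v), int(s)) for v, s in zip(viable, selected)]
    return CultureSet(
        strain_id="synthetic",
        condition=condition,
        cultures=cultures,
        plating_fraction=cfg.plating_fraction,
    )


# ---------------------------------------------------------------------------
# Reference sequence with planted repeats


def _random_base_not(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def _build_candidate(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, list[tuple[int, int, int]]]:
    seq = list(rng.choice(_BASES, size=cfg.ref_length))
    placements: list[tuple[int, int, int]] = []  # (q0, motif_len, spacing)
    span_total = sum(r.spacing + r.motif_len + 5 for r in cfg.repeat_plan) + 10
    if span_total > cfg.ref_length:
        raise SimulationError(
            f"repeat plan needs {span_total} nt but ref_length is {cfg.ref_length}"
        )
    cursor = 5
    slack = cfg.ref_length - span_total
    for spec in cfg.repeat_plan:
        cursor += int(rng.integers(0, max(slack // max(len(cfg.repeat_plan), 1), 1) + 1))
        q0, k, d = cursor, spec.motif_len, spec.spacing
        seq[q0 + d : q0 + d + k] = seq[q0 : q0 + k]  # second repeat copy
        # enforce left-maximality and an exact micro-homology of k
        if seq[q0 - 1] == seq[q0 + d - 1]:
            seq[q0 - 1] = _random_base_not(rng, seq[q0 + d - 1])
        if q0 + d + k < cfg.ref_length and seq[q0 + k] == seq[q0 + d + k]:
            seq[q0 + d + k] = _random_base_not(rng, seq[q0 + k])
        placements.append((q0, k, d))
        cursor += d + k + 5
    return "".join(seq), placements


def _spurious_repeats(seq: str, planted: Iterable[tuple[int, int, int]]) -> bool:
    kmers: dict[str, int] = {}
    k = SPURIOUS_REPEAT_LEN
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in kmers:
            return True
        kmers[kmer] = i
    return False


def generate_reference(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    return_placements: bool = False,
):
    """Random ORF-scale reference with planted direct-repeat pairs.

    Each plan entry places a motif twice at the requested start-to-start
    spacing; flanking bases are adjusted so the pair is left-maximal and
    its micro-homology is exactly the motif length.  Candidates with any
    unintended exact repeat of >= 12 nt are rejected and re-drawn.
    """
    if cfg.ref_length < 100:
        raise SimulationError("ref_length must be >= 100")
    if rng is None:
        rng = rng_for(cfg.seed, "reference")
    for _ in range(200):
        seq, placements = _build_candidate(cfg, rng)
        if not _spurious_repeats(seq, placements):
            if return_placements:
                return seq, placements
            return seq
    raise SimulationError("could not generate a reference without spurious repeats")


def find_repeat_pairs(ref: str, spacing: Optional[int] = None) -> list[tuple[int, int, int]]:
    """Scan a reference for left-maximal direct-repeat pairs.

    Returns (q0, motif_len, spacing) triples, 0-based, where
    ``ref[q0 : q0+motif_len] == ref[q0+spacing : q0+spacing+motif_len]``,
    the match length is maximal, and the pair cannot be shifted left.
    Restricted to the requested spacing when given.
    """
    n = len(ref)
    spacings = [spacing] if spacing is not None else range(2, 51)
    pairs = []
    for d in spacings:
        for q0 in range(n - d):
            if ref[q0] != ref[q0 + d]:
                continue
            if q0 > 0 and ref[q0 - 1] == ref[q0 + d - 1]:
                continue  # not left-aligned
            m = 0
            while q0 + d + m < n and ref[q0 + m] == ref[q0 + d + m]:
                m += 1
            if 1 <= m <= 10 and m < d:
                pairs.append((q0, m, d))
    return pairs


# ---------------------------------------------------------------------------
# Planted events


def _runs(ref: str) -> list[tuple[int, int]]:
    """(start, length) of maximal homopolymer runs, 0-based."""
    runs = []
    i = 0
    while i < len(ref):
        j = i
        while j < len(ref) and ref[j] == ref[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


_SUB_TEMPLATES = {
    "GC->AT": {"G": "A", "C": "T"},
    "AT->GC": {"A": "G", "T": "C"},
    "GC->TA": {"G": "T", "C": "A"},
    "GC->CG": {"G": "C", "C": "G"},
    "AT->CG": {"A": "C", "T": "G"},
    "AT->TA": {"A": "T", "T": "A"},
}


def plant_event(
    ref: str,
    event_spec: EventSpec,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[str, TruthRecord]:
    """Introduce one event of the requested category into the reference.

    Slippage events use a planted repeat pair: a deletion removes the
    segment from the first repeat start up to (not including) the second
    repeat start, retaining one repeat copy; a duplication inserts a
    tandem copy of that segment.  Substitutions and frameshifts are
    placed at positions honouring the requested class and run context.
    Returns the mutant sequence and the planted ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    kind = event_spec.kind

    if kind in _SUB_TEMPLATES:
        table = _SUB_TEMPLATES[kind]
        positions = [i for i, b in enumerate(ref) if b in table]
        if not positions:
            raise SimulationError(f"no position available for class {kind}")
        i = positions[rng.integers(len(positions))]
        mut = ref[:i] + table[ref[i]] + ref[i + 1 :]
        return mut, TruthRecord("", "mutation", "substitution", i + 1, 1, 0)

    if kind in ("fs_plus_homo", "fs_minus_homo"):
        runs = [(s, l) for s, l in _runs(ref) if l >= 2]
        if not runs:
            raise SimulationError("reference has no homopolymer run of >= 2")
        s, l = runs[rng.integers(len(runs))]
        if kind == "fs_plus_homo":
            # reference-frame micro-homology of a run insertion is run-1
            mut = ref[:s] + ref[s] + ref[s:]
            return mut, TruthRecord("", "mutation", "frameshift_ins", s + 1, 1, l - 1)
        mut = ref[:s] + ref[s + 1 :]
        return mut, TruthRecord("", "mutation", "frameshift_del", s + 1, 1, l - 1)

    if kind in ("fs_plus_mono", "fs_minus_mono"):
        singles = [s for s, l in _runs(ref) if l == 1 and 0 < s < len(ref) - 1]
        if not singles:
            raise SimulationError("reference has no isolated base")
        s = singles[rng.integers(len(singles))]
        if kind == "fs_minus_mono":
            mut = ref[:s] + ref[s + 1 :]
            return mut, TruthRecord("", "mutation", "frameshift_del", s + 1, 1, 0)
        base = _random_base_not(rng, ref[s], ref[s - 1])
        mut = ref[:s] + base + ref[s:]
        return mut, TruthRecord("", "mutation", "frameshift_ins", s + 1, 1, 0)

    if kind in ("deletions", "duplications"):
        pairs = find_repeat_pairs(ref, event_spec.size)
        if not pairs:
            raise SimulationError(
                f"no compatible repeat pair (spacing={event_spec.size}) in reference"
            )
        q0, k, d = pairs[rng.integers(len(pairs))]
        if kind == "deletions":
            mut = ref[:q0] + ref[q0 + d :]
            return mut, TruthRecord("", "mutation", "deletion", q0 + 1, d, k)
        mut = ref[: q0 + d] + ref[q0:]
        return mut, TruthRecord("", "mutation", "duplication", q0 + 1, d, k)

    raise SimulationError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# Colony populations


def simulate_colony_population(
    cfg: SimConfig,
    n_colonies: int,
    condition: Condition = Condition.RFB_ON,
    rng: Optional[np.random.Generator] = None,
    flag_flip_noise: float = 0.0,
) -> tuple[list[ColonyAssay], list[TruthRecord]]:
    """Draw a population of selected colonies from the event mixture.

    Deletion and translocation colonies receive the corresponding PCR
    amplification patterns; mutation colonies carry a mutant allele with
    one planted spectrum event.  ``flag_flip_noise`` flips each
    amplification flag independently with the given probability,
    emulating PCR failure or contamination.
    """
    condition = Condition(condition)
    if rng is None:
        rng = rng_for(cfg.seed, f"colonies/{condition.value}")
    ref = generate_reference(cfg, rng_for(cfg.seed, "reference"))

    classes = list(cfg.event_mixture)
    class_p = np.array([cfg.event_mixture[c] for c in classes])
    cats = list(cfg.mutation_spectrum)
    cat_p = np.array([cfg.mutation_spectrum[c] for c in cats])

    assays: list[ColonyAssay] = []
    truths: list[TruthRecord] = []
    for i in range(n_colonies):
        cid = f"{condition.value.lower()}-{i:05d}"
        cls = classes[rng.choice(len(classes), p=class_p)]
        if cls == "deletion":
            flags = [False, True, False]
            seq = None
            truth = TruthRecord(cid, "deletion")
        elif cls == "translocation":
            flags = [False, True, True]
            seq = None
            truth = TruthRecord(cid, "translocation")
        else:
            cat = cats[rng.choice(len(cats), p=cat_p)]
            seq, truth = plant_event(ref, EventSpec(cat), rng)
            truth = replace(truth, colony_id=cid)
            flags = [True, True, False]
        if flag_flip_noise > 0:
            flips = rng.random(3) < flag_flip_noise
            flags = [f ^ bool(fl) for f, fl in zip(flags, flips)]
            if not flags[0]:
                seq = None
        assays.append(
            ColonyAssay(
                colony_id=cid,
                ura4_amplified=flags[0],
                rng3_amplified=flags[1],
                tl_junction_amplified=flags[2],
                ura4_sequence=seq,
            )
        )
        truths.append(truth)
    return assays, truths


# ---------------------------------------------------------------------------
# Kinetics


def simulate_kinetics(
    cfg: SimConfig,
    generation_grid: Optional[Sequence[float]] = None,
    rng: Optional[np.random.Generator] = None,
    strain_id: str = "synthetic",
) -> KineticsSeries:
    """Linear revertant-frequency kinetics with multiplicative noise.

    f(g) = baseline + rate * g, observed with relative Gaussian noise of
    sd ``noise_sd`` (clipped at zero), for ``n_experiments`` independent
    experiments on the same generation grid.
    """
    if generation_grid is None:
        generation_grid = np.arange(0, 24, 4, dtype=float)
    grid = np.asarray(generation_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise SimulationError("generation grid must be strictly increasing")
    if rng is None:
        rng = rng_for(cfg.seed, "kinetics")
    experiments = []
    for _ in range(cfg.n_experiments):
        f = cfg.kinetics_baseline + cfg.kinetics_rate * grid
        obs = f * (1.0 + cfg.noise_sd * rng.standard_normal(grid.size))
        experiments.append(np.column_stack([grid, np.clip(obs, 0.0, None)]))
    return KineticsSeries(strain_id=strain_id, experiments=experiments)
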