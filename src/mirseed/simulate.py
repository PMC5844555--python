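"""Seeded synthetic screens and sequence fixtures with known ground truth.

The plate generator emulates the screen's structure: one gene per 96-well
plate, six plates per gene, a ~470-mimic miRNA library distributed
round-robin over the plates, 4 non-targeting and 4 vehicle controls per
plate, duplicate or triplicate screening per gene.  Well-level log2
normalized reporter activity is composed additively:

    NRA = gene baseline + plate offset + miRNA bias + interaction effect
          + edge field + noise

with interaction effects ≤ 0 (repression) for a sparse random subset of
(miRNA, gene) pairs.  Renilla luminescence is simulated independently and
firefly reconstructed from the NRA, so the ratio normalization downstream is
actually exercised.  Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NTC, PLATE_ROWS, VEHICLE, SequenceRecord
from .sites import (
    COMPLEMENT,
    MISMATCH_CLASSES,
    SITE_CLASSES,
    reverse_complement,
    scan_pair,
)

#: the 17 screened cancer genes; TP53 and PHF6 were screened in triplicate
DEFAULT_GENES = (
    "ALK", "BRCA1", "BRCA2", "EZH2", "FBXW7", "HRAS", "MYB", "MYC", "MYCN",
    "MYT1L", "NOTCH1", "PALB2", "PHF6", "PHOX2B", "RB1", "TP53", "ZEB2",
)
TRIPLICATE_GENES = ("PHF6", "TP53")

BASES = "ACGU"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 470 miRNAs × 17 genes ≈ 7990 probed pairs,
    ~4.9% of them true interactions."""

    n_mirnas: int = 470
    genes: Sequence[str] = DEFAULT_GENES
    plates_per_gene: int = 6
    n_ntc: int = 4
    n_vehicle: int = 4
    replicates: int | Mapping[str, int] | None = None  # None → study design
    interaction_prevalence: float = 0.049
    effect_mean: float = -3.0
    effect_sd: float = 0.5
    mirna_bias_sd: float = 0.5
    gene_baseline_sd: float = 0.5
    plate_sd: float = 0.25
    noise_sd: float = 0.5
    edge_effect: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.interaction_prevalence <= 1.0:
            raise SimulationError("interaction_prevalence must lie in [0, 1]")
        for name in ("effect_sd", "mirna_bias_sd", "gene_baseline_sd",
                     "plate_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        per_plate = 96 - self.n_ntc - self.n_vehicle
        capacity = per_plate * self.plates_per_gene
        if self.n_mirnas > capacity:
            raise SimulationError(
                f"infeasible layout: {self.n_mirnas} miRNAs exceed "
                f"{capacity} treatment wells per gene"
            )

    def replicates_for(self, gene: str) -> int:
        if self.replicates is None:
            return 3 if gene in TRIPLICATE_GENES else 2
        if isinstance(self.replicates, int):
            return self.replicates
        return self.replicates[gene]


@dataclass(frozen=True)
class ScreenTruth:
    """Simulation ground truth behind a generated screen."""

    interactions: dict[tuple[str, str], float]  # (miRNA, gene) → effect ≤ 0
    mirna_bias: dict[str, float]
    plate_offsets: dict[str, float]
    gene_baselines: dict[str, float]
    edge_effect: float
    mirnas: tuple[str, ...] = ()
    config: SimConfig | None = None


def mirna_ids(n: int) -> list[str]:
    return [f"sim-miR-{i:04d}" for i in range(1, n + 1)]


def _plate_layout(n_mirnas_on_plate: int, n_ntc: int, n_vehicle: int):
    """Well positions: treatments fill columns 1–11 row-major; controls sit
    in column 12 (NTC on top, vehicle below)."""
    positions = [(PLATE_ROWS[t // 11], t % 11 + 1) for t in range(n_mirnas_on_plate)]
    ctrl = [(PLATE_ROWS[i], 12) for i in range(n_ntc + n_vehicle)]
    return positions, ctrl[:n_ntc], ctrl[n_ntc:]


def generate_screen(
    config: SimConfig | None = None,
    shared_bias: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate one full reporter screen; returns (wells, truth).

    ``shared_bias`` reuses another screen's per-miRNA biases, mimicking the
    same physical mimic library being screened again (as for the empty-3'UTR
    negative-control screen).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    mirnas = mirna_ids(cfg.n_mirnas)
    genes = list(cfg.genes)

    baselines = dict(zip(genes, rng.normal(0.0, cfg.gene_baseline_sd, len(genes))))
    bias = dict(zip(mirnas, rng.normal(0.0, cfg.mirna_bias_sd, len(mirnas))))
    if shared_bias is not None:
        bias = {m: shared_bias[m] for m in mirnas}

    hit = rng.random((len(mirnas), len(genes))) < cfg.interaction_prevalence
    effect_draws = rng.normal(cfg.effect_mean, cfg.effect_sd, hit.shape)
    interactions = {
        (mirnas[i], genes[j]): float(min(0.0, effect_draws[i, j]))
        for i, j in zip(*np.nonzero(hit))
    }

    rows: list[tuple] = []
    plate_offsets: dict[str, float] = {}
    for gene in genes:
        for rep in range(1, cfg.replicates_for(gene) + 1):
            for k in range(cfg.plates_per_gene):
                plate = f"{gene}-r{rep}-p{k + 1}"
                offset = float(rng.normal(0.0, cfg.plate_sd))
                plate_offsets[plate] = offset
                plate_mirnas = mirnas[k :: cfg.plates_per_gene]
                mpos, ntc_pos, veh_pos = _plate_layout(
                    len(plate_mirnas), cfg.n_ntc, cfg.n_vehicle
                )
                wells = (
                    list(zip(plate_mirnas, mpos))
                    + [(NTC, p) for p in ntc_pos]
                    + [(VEHICLE, p) for p in veh_pos]
                )
                noise = rng.normal(0.0, cfg.noise_sd, len(wells))
                log10_rluc = rng.normal(5.0, 0.15, len(wells))
                for (treatment, (row, col)), eps, lr in zip(wells, noise, log10_rluc):
                    nra = baselines[gene] + offset + eps
                    if treatment not in (NTC, VEHICLE):
                        nra += bias[treatment]
                        nra += interactions.get((treatment, gene), 0.0)
                    if cfg.edge_effect and (row in "AH" or col in (1, 12)):
                        nra += cfg.edge_effect
                    rluc = 10.0 ** lr
                    rows.append(
                        (gene, rep, plate, row, col, treatment, rluc * 2.0 ** nra, rluc)
                    )

    wells = pd.DataFrame(
        rows,
        columns=["gene", "replicate", "plate", "row", "column",
                 "treatment", "luc2P", "Rluc"],
    )
    wells["usable"] = True
    truth = ScreenTruth(
        interactions=interactions,
        mirna_bias=bias,
        plate_offsets=plate_offsets,
        gene_baselines=baselines,
        edge_effect=cfg.edge_effect,
        mirnas=tuple(mirnas),
        config=cfg,
    )
    return wells, truth


def generate_empty_screen(
    config: SimConfig | None = None,
    shared_truth: ScreenTruth | None = None,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Duplicate screen of the library on a reporter with no 3' UTR insert.

    No pair can interact (prevalence forced to 0); per-miRNA biases are
    reused from ``shared_truth`` when given, since the same mimic library is
    screened.  Serves as the ROC negative-control score source.
    """
    cfg = config or SimConfig()
    cfg = dc_replace(
        cfg,
        genes=("EMPTY",),
        interaction_prevalence=0.0,
        replicates=2,
    )
    return generate_screen(
        cfg, shared_bias=shared_truth.mirna_bias if shared_truth else None
    )


# ---------------------------------------------------------------------------
# sequence fixtures


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def _build_implant(cls: str, mir: str, rng: np.random.Generator):
    """Core target pattern plus flanking-base constraints for one site class.

    Returns (pattern, forbidden_before, forbidden_after): the pattern placed
    in the UTR spans exactly the coordinates the scanner reports, and the
    guards forbid flanking bases that would upgrade or destroy the class
    (e.g. an offset-6mer locus gets a guaranteed nt-2 mismatch).
    """
    perfect = reverse_complement(mir[1:7])  # seed target, 5'→3'
    c8 = COMPLEMENT[mir[7]]
    if cls == "8mer":
        return reverse_complement(mir[1:8]) + "A", set(), set()
    if cls == "7mer-m8":
        return reverse_complement(mir[1:8]), set(), {"A"}
    if cls == "7mer-A1":
        return perfect + "A", {c8}, set()
    if cls == "6mer":
        return perfect, {c8}, {"A"}
    if cls == "offset6":
        return reverse_complement(mir[2:8]), set(), {COMPLEMENT[mir[1]]}
    if cls in MISMATCH_CLASSES:
        if cls == "gu_wobble":
            ks = [k for k in range(2, 8) if mir[k - 1] in "GU"]
            if not ks:
                raise SimulationError("miRNA seed has no G/U position to wobble")
            k = int(rng.choice(ks))
            sub = "U" if mir[k - 1] == "G" else "G"
        else:
            k = int(rng.integers(2, 8))
            banned = {COMPLEMENT[mir[k - 1]]}
            if mir[k - 1] == "G":
                banned.add("U")
            elif mir[k - 1] == "U":
                banned.add("G")
            sub = str(rng.choice([b for b in BASES if b not in banned]))
        idx = 7 - k  # position of the nt-k target base in the 6-mer
        return perfect[:idx] + sub + perfect[idx + 1 :], set(), set()
    if cls == "gbulge":
        return perfect[:2] + "G" + perfect[2:], set(), set()
    if cls == "centered":
        if len(mir) < 15:
            raise SimulationError("centered implant needs a miRNA of length >= 15")
        # guards stop the paired run at exactly nt 4–14 and block a seed match
        return (
            reverse_complement(mir[3:14]),
            {COMPLEMENT[mir[14]]},
            {COMPLEMENT[mir[2]]},
        )
    raise SimulationError(f"unknown site class {cls!r}")


def _place_implants(
    mir: str,
    utr_length: int,
    implant_spec: Sequence[tuple[str, int]],
    rng: np.random.Generator,
):
    """One candidate UTR with all requested implants at non-overlapping loci."""
    implants = []
    for cls, count in implant_spec:
        for _ in range(count):
            implants.append((cls, *_build_implant(cls, mir, rng)))
    seq = list(_random_seq(rng, utr_length))
    occupied = np.zeros(utr_length + 2, dtype=bool)  # 1-based, with margins
    truth = []
    for cls, pattern, pre, post in implants:
        span = len(pattern) + 2  # pattern plus guard bases either side
        if span > utr_length:
            raise SimulationError("utr_length too small for requested implants")
        for _ in range(200):
            start = int(rng.integers(2, utr_length - len(pattern) + 1))
            if not occupied[start - 2 : start + len(pattern) + 1].any():
                break
        else:
            raise SimulationError("could not place implants without overlap")
        # reserve the pattern plus both guard positions (0-based slice)
        occupied[start - 2 : start + len(pattern) + 1] = True
        seq[start - 1 : start - 1 + len(pattern)] = pattern
        seq[start - 2] = str(rng.choice([b for b in BASES if b not in pre]))
        after = start - 1 + len(pattern)
        if after < utr_length:
            seq[after] = str(rng.choice([b for b in BASES if b not in post]))
        truth.append((cls, start, start + len(pattern) - 1))
    return "".join(seq), truth


def generate_sequence_fixtures(
    n_mirnas: int,
    n_utrs: int,
    utr_length: int,
    implant_spec: Sequence[tuple[str, int]] = (),
    rng_seed: int = 0,
    max_tries: int = 200,
):
    """Random miRNA/UTR pairs with implanted binding sites of known class.

    UTR ``j`` is paired with miRNA ``j % n_mirnas`` and carries the implants
    in ``implant_spec`` (list of (site_class, count)).  Backgrounds are
    resampled until every implanted site is recovered by the scanner and no
    site of an implanted class occurs away from the implanted loci — so the
    truth table is a complete site list for those classes up to sites the
    implants themselves entail at overlapping registers (an offset 6mer, for
    instance, always doubles as a seed-mismatch window one register over).
    With an empty spec the UTRs are pure random background.

    Returns (miRNA records, UTR records, truth DataFrame).
    """
    rng = np.random.default_rng(rng_seed)
    mirnas = [
        SequenceRecord(f"fix-miR-{i + 1:03d}", _random_seq(rng, 22), "miRNA")
        for i in range(n_mirnas)
    ]
    classes = tuple({cls for cls, _ in implant_spec})
    utrs: list[SequenceRecord] = []
    truth_rows: list[tuple] = []
    for j in range(n_utrs):
        mir = mirnas[j % n_mirnas]
        uid = f"fix-utr-{j + 1:03d}"
        if not implant_spec:
            utrs.append(SequenceRecord(uid, _random_seq(rng, utr_length), "UTR"))
            continue
        for _ in range(max_tries):
            seq, truth = _place_implants(mir.residues, utr_length, implant_spec, rng)
            utr = SequenceRecord(uid, seq, "UTR")
            found = {
                (s.site_class, s.start, s.end)
                for s in scan_pair(mir, utr, classes=classes)
            }
            truth_set = set(truth)
            overlaps_implant = lambda s, e: any(  # noqa: E731
                s <= te and e >= ts for _, ts, te in truth
            )
            if truth_set <= found and all(
                f in truth_set or overlaps_implant(f[1], f[2]) for f in found
            ):
                break
        else:
            raise SimulationError(
                f"could not build a clean fixture for {uid} in {max_tries} tries"
            )
        utrs.append(utr)
        truth_rows += [(mir.id, uid, cls, s, e) for cls, s, e in truth]
    truth_table = pd.DataFrame(
        truth_rows, columns=["mirna", "utr", "site_class", "start", "end"]
    )
    return mirnas, utrs, truth_table
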