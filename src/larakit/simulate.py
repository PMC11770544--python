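"""Synthetic inputs for every pipeline stage.

Four generators, each seeded and deterministic:

* LarA-like protein families carrying the diagnostic active-site residues of
  the five functional families (LAR, MAR, GntE, HGR, HHR) on a shared
  pseudo-random scaffold, with point mutations and indels;
* Michaelis–Menten initial rates with multiplicative Gaussian noise;
* pairwise competition rate ratios derived from a hidden kcat/KM table with
  lognormal noise;
* per-taxon species gene-copy-number tables.

Scaffold design.  A single 430-residue pseudo-random base scaffold (a fixed
package constant, *not* any real sequence) carries the invariant active-site
anchors at LarA1-equivalent coordinates: R75, H108, H174, K184, H200 plus the
four diagnostic positions 175/176/358/359.  Each family is a fixed variant of
the base scaffold in which 55% of unconstrained positions are substituted.
That makes within-family identity high (~0.95 at mutation rate 0.05) and
between-family identity low (~0.25), so identity-threshold clustering at 0.5
separates families, while the sequences remain globally alignable to the
packaged LarA1-numbered reference for signature extraction.  Real superfamily
members are related by descent, not by this two-level construction — see the
methods note for what that does and does not let the tests show.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS
from .repertoire import ProteinRecord

__all__ = [
    "FAMILIES",
    "SCAFFOLD_LENGTH",
    "ANCHOR_RESIDUES",
    "DIAGNOSTIC_POSITIONS",
    "SequenceSimSpec",
    "KineticsSimSpec",
    "CompetitionSimSpec",
    "reference_record",
    "simulate_family_sequences",
    "simulate_initial_rates",
    "simulate_competition",
    "simulate_taxonomy",
    "true_family",
    "write_assay_tsv",
    "write_competition_tsv",
    "write_taxonomy_tsv",
]

SCAFFOLD_LENGTH = 430

# Invariant active-site anchors at LarA1-equivalent coordinates (1-based):
# cofactor binding R75/K184/H200 and the two catalytic histidines 108/174.
ANCHOR_RESIDUES: dict[int, str] = {75: "R", 108: "H", 174: "H", 184: "K", 200: "H"}

# Substrate-selectivity diagnostic positions (LarA1 numbering).
DIAGNOSTIC_POSITIONS: tuple[int, int, int, int] = (175, 176, 358, 359)

FAMILIES = ("LAR", "MAR", "GntE", "HGR", "HHR")

# Per-family residues at the diagnostic positions.  A multi-letter string is
# a per-record choice set; None leaves the family scaffold's background
# residue in place (the positions the residue rules leave unconstrained).
_FAMILY_SIGNATURES: dict[str, tuple[str | None, str | None, str | None, str | None]] = {
    "LAR": ("F", "F", "W", "EQ"),
    "MAR": (None, None, "HQ", "K"),
    "GntE": ("E", "V", "A", "H"),
    "HGR": ("Y", "F", "HQ", "T"),
    "HHR": (None, None, "FY", None),
}

# LarA1 itself: F175, F176, W358, T359 on the base scaffold.
_REFERENCE_DIAGNOSTIC = {175: "F", 176: "F", 358: "W", 359: "T"}

_SCAFFOLD_SEED = 20_882_088  # package constant; scaffolds are fixed, not user-seeded
_FAMILY_DIVERGENCE = 0.55
_MOTIF_FLANK = 3  # residues around each active-site position conserved across families

_CONSTRAINED = tuple(sorted(set(ANCHOR_RESIDUES) | set(DIAGNOSTIC_POSITIONS)))

# Active-site positions plus their motif flanks: conserved between family
# scaffolds (as real catalytic motifs are), so that cross-family alignment to
# the LarA1-numbered reference maps the diagnostic coordinates reliably.
# User-level mutations may still hit the flanks — only _CONSTRAINED positions
# themselves are immutable.
_MOTIF_POSITIONS = frozenset(
    p
    for center in _CONSTRAINED
    for p in range(center - _MOTIF_FLANK, center + _MOTIF_FLANK + 1)
    if 1 <= p <= SCAFFOLD_LENGTH
)


def _substitute(rng: np.random.Generator, residue: str) -> str:
    choices = AMINO_ACIDS.replace(residue, "")
    return choices[rng.integers(len(choices))]


@functools.lru_cache(maxsize=1)
def _base_scaffold() -> str:
    rng = np.random.default_rng(_SCAFFOLD_SEED)
    letters = np.array(list(AMINO_ACIDS))
    seq = list("".join(rng.choice(letters, size=SCAFFOLD_LENGTH)))
    for pos, res in ANCHOR_RESIDUES.items():
        seq[pos - 1] = res
    return "".join(seq)


@functools.lru_cache(maxsize=None)
def _family_scaffold(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    rng = np.random.default_rng(_SCAFFOLD_SEED + 9973 * (FAMILIES.index(family) + 1))
    seq = list(_base_scaffold())
    for i in range(SCAFFOLD_LENGTH):
        if (i + 1) not in _MOTIF_POSITIONS and rng.random() < _FAMILY_DIVERGENCE:
            seq[i] = _substitute(rng, seq[i])
    for pos, sig in zip(DIAGNOSTIC_POSITIONS, _FAMILY_SIGNATURES[family]):
        if sig is not None and len(sig) == 1:
            seq[pos - 1] = sig
    return "".join(seq)


@functools.lru_cache(maxsize=1)
def reference_record() -> ProteinRecord:
    """The packaged LarA1-numbered reference scaffold (F, F, W, T at
    175/176/358/359 plus the binding/catalytic anchors)."""
    seq = list(_base_scaffold())
    for pos, res in _REFERENCE_DIAGNOSTIC.items():
        seq[pos - 1] = res
    return ProteinRecord(
        id="LarA1_scaffold",
        sequence="".join(seq),
        description="synthetic LarA1-numbered reference scaffold",
    )


@dataclass(frozen=True)
class SequenceSimSpec:
    """Specification for one family's synthetic sequence set."""

    family: str
    n_sequences: int
    scaffold_length: int = SCAFFOLD_LENGTH
    mutation_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be in [0, 1]")
        if not (0 <= self.indel_rate <= 1):
            raise ValueError("indel_rate must be in [0, 1]")
        if self.scaffold_length != SCAFFOLD_LENGTH:
            raise ValueError(
                "only the packaged scaffold length "
                f"({SCAFFOLD_LENGTH}) is supported"
            )
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be non-negative")


def _apply_indel(rng: np.random.Generator, seq: list[str]) -> list[str]:
    """One insertion or deletion of 1–5 residues, never touching a
    constrained position (deletions) so ground truth stays defined."""
    length = int(rng.integers(1, 6))
    if rng.random() < 0.5:  # insertion: anywhere between residues
        pos = int(rng.integers(0, len(seq) + 1))
        insert = [AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(length)]
        return seq[:pos] + insert + seq[pos:]
    constrained = set(_CONSTRAINED)
    starts = [
        s
        for s in range(len(seq) - length + 1)
        if not any((s + k + 1) in constrained for k in range(length))
    ]
    if not starts:
        return seq
    s = starts[int(rng.integers(len(starts)))]
    return seq[:s] + seq[s + length :]


def simulate_family_sequences(spec: SequenceSimSpec) -> list[ProteinRecord]:
    """Generate signature-bearing sequences for one family.

    Records are tagged with the generating family in the description
    (``family=...``) for downstream accuracy checks; see :func:`true_family`.
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = _family_scaffold(spec.family)
    constrained = set(_CONSTRAINED)
    records: list[ProteinRecord] = []
    for i in range(spec.n_sequences):
        seq = list(scaffold)
        for pos, sig in zip(DIAGNOSTIC_POSITIONS, _FAMILY_SIGNATURES[spec.family]):
            if sig is not None and len(sig) > 1:
                seq[pos - 1] = sig[rng.integers(len(sig))]
        if spec.mutation_rate > 0:
            hits = rng.random(len(seq)) < spec.mutation_rate
            for j in np.flatnonzero(hits):
                if (j + 1) not in constrained:
                    seq[j] = _substitute(rng, seq[j])
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            seq = _apply_indel(rng, seq)
        records.append(
            ProteinRecord(
                id=f"{spec.family}_{spec.seed}_{i:04d}",
                sequence="".join(seq),
                description=f"family={spec.family}",
            )
        )
    return records


def true_family(record: ProteinRecord) -> str | None:
    """Ground-truth family tag of a simulated record, if present."""
    for token in record.description.split():
        if token.startswith("family="):
            return token.split("=", 1)[1]
    return None


@dataclass(frozen=True)
class KineticsSimSpec:
    """Michaelis–Menten initial-rate simulation.

    Velocities are ``kcat * E0 * S / (Km + S)`` with multiplicative Gaussian
    noise of coefficient of variation ``noise_cv`` (assay error scales with
    signal).  Units: Km and the grid in mM, kcat in 1/s, enzyme in µM, so
    velocities come out in µM/s.
    """

    Km_true: float
    kcat_true: float
    enzyme_conc: float = 0.1
    substrate_grid: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 20.0)
    noise_cv: float = 0.05
    replicates: int = 3
    substrate: str = "S"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Km_true <= 0 or self.kcat_true <= 0 or self.enzyme_conc <= 0:
            raise ValueError("Km_true, kcat_true and enzyme_conc must be positive")
        if not self.substrate_grid:
            raise ValueError("substrate_grid must be non-empty")
        if any(s <= 0 for s in self.substrate_grid):
            raise ValueError("substrate concentrations must be positive")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("noise_cv must be >= 0 and replicates >= 1")


def simulate_initial_rates(spec: KineticsSimSpec):
    """Generate noisy initial-rate measurements on the specified grid."""
    from .kinetics import RateMeasurement

    rng = np.random.default_rng(spec.seed)
    out = []
    for rep in range(spec.replicates):
        for s in spec.substrate_grid:
            v = spec.kcat_true * spec.enzyme_conc * s / (spec.Km_true + s)
            if spec.noise_cv > 0:
                v *= 1.0 + rng.normal(0.0, spec.noise_cv)
            out.append(
                RateMeasurement(
                    substrate=spec.substrate,
                    concentration=float(s),
                    velocity=float(v),
                    enzyme_conc=spec.enzyme_conc,
                    replicate=rep,
                )
            )
    return out


@dataclass(frozen=True)
class CompetitionSimSpec:
    """Pairwise competition assays from a hidden kcat/KM table.

    For a pair (X, Y) the observed rate ratio is
    ``vx/vy = (kx [Sx]) / (ky [Sy])`` times lognormal noise of coefficient of
    variation ``noise_cv`` (lognormal keeps ratios positive).  The 30 mM
    default concentration is the standard assay substrate loading.
    """

    true_efficiencies: tuple[tuple[str, float], ...]
    pair_design: tuple[tuple[str, str], ...]
    conc_x: float = 30.0
    conc_y: float = 30.0
    noise_cv: float = 0.05
    replicates: int = 3
    enzyme: str = "enzyme"
    seed: int = 0

    def __post_init__(self) -> None:
        effs = dict(self.true_efficiencies)
        if not effs:
            raise ValueError("true_efficiencies must be non-empty")
        if any(v <= 0 for v in effs.values()):
            raise ValueError("true efficiencies must be strictly positive")
        unknown = [
            s for pair in self.pair_design for s in pair if s not in effs
        ]
        if unknown:
            raise ValueError(
                f"pair_design references unknown substrate(s): {sorted(set(unknown))}"
            )
        if self.conc_x <= 0 or self.conc_y <= 0:
            raise ValueError("concentrations must be positive")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValueError("noise_cv must be >= 0 and replicates >= 1")

    @property
    def efficiencies(self) -> dict[str, float]:
        return dict(self.true_efficiencies)


def simulate_competition(spec: CompetitionSimSpec):
    """Generate competition observations for every pair in the design."""
    from .competition import CompetitionObservation

    rng = np.random.default_rng(spec.seed)
    effs = spec.efficiencies
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    out = []
    for rep in range(spec.replicates):
        for x, y in spec.pair_design:
            ratio = (effs[x] * spec.conc_x) / (effs[y] * spec.conc_y)
            if spec.noise_cv > 0:
                ratio *= float(np.exp(rng.normal(0.0, sigma)))
            out.append(
                CompetitionObservation(
                    enzyme=spec.enzyme,
                    substrate_x=x,
                    substrate_y=y,
                    conc_x=spec.conc_x,
                    conc_y=spec.conc_y,
                    vx=float(ratio),
                    vy=1.0,
                    replicate=rep,
                )
            )
    return out


def simulate_taxonomy(
    taxa_spec: Sequence[tuple[str, int, float, int | Callable]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species gene copy-number table.

    ``taxa_spec`` rows are ``(taxon, n_species, carrier_fraction,
    copy_distribution)`` where ``copy_distribution`` is either a constant
    copy number for carriers or a callable ``f(rng, size) -> int array``
    returning counts >= 1.

    Returns a DataFrame with columns ``species``, ``taxon``, ``n_genes``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for taxon, n_species, carrier_fraction, copy_dist in taxa_spec:
        if n_species < 0:
            raise ValueError(f"negative n_species for taxon {taxon!r}")
        if not (0 <= carrier_fraction <= 1):
            raise ValueError(f"carrier_fraction out of [0,1] for taxon {taxon!r}")
        carriers = rng.random(n_species) < carrier_fraction
        n_carriers = int(carriers.sum())
        if callable(copy_dist):
            copies = np.asarray(copy_dist(rng, n_carriers), dtype=int)
            if len(copies) != n_carriers or (n_carriers and copies.min() < 1):
                raise ValueError("copy_distribution must return size counts >= 1")
        else:
            if int(copy_dist) < 1:
                raise ValueError("constant copy number must be >= 1")
            copies = np.full(n_carriers, int(copy_dist))
        counts = np.zeros(n_species, dtype=int)
        counts[carriers] = copies
        for i in range(n_species):
            rows.append((f"{taxon}_sp{i:05d}", taxon, int(counts[i])))
    return pd.DataFrame(rows, columns=["species", "taxon", "n_genes"])


def write_assay_tsv(measurements, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write initial-rate measurements in the pipeline's assay schema."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("enzyme\tsubstrate\tconc_mM\tvelocity\tenzyme_conc_uM\treplicate\n")
        for m in measurements:
            enzyme = getattr(m, "enzyme", "enzyme")
            fh.write(
                f"{enzyme}\t{m.substrate}\t{m.concentration!r}\t{m.velocity!r}"
                f"\t{m.enzyme_conc!r}\t{m.replicate}\n"
            )


def write_competition_tsv(observations, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write competition observations in the pipeline's competition schema."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "enzyme\tsubstrate_x\tsubstrate_y\tconc_x_mM\tconc_y_mM\tvx\tvy\treplicate\n"
        )
        for o in observations:
            fh.write(
                f"{o.enzyme}\t{o.substrate_x}\t{o.substrate_y}\t{o.conc_x!r}"
                f"\t{o.conc_y!r}\t{o.vx!r}\t{o.vy!r}\t{o.replicate}\n"
            )


def write_taxonomy_tsv(table: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a species gene-count table as TSV."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)
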