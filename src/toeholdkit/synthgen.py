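"""Deterministic generators for barcode gene families and plate kinetics.

These emulate the study conditions every stage is tested against: a panel of
species sharing three homologous barcode markers (MatK, RbcL, TrnL-UAA) that
differ from the reference by per-site substitutions, and plate-reader traces
with a known true ON/OFF fold change.  All randomness is seeded; the same
spec and seed reproduce identical outputs byte for byte.

The substitution model is Jukes-Cantor-like (uniform over the three
alternative bases, no indels) so that downstream mismatch counting on
equal-length windows is exact ground truth.  Kinetics are saturating
exponentials — reactions approach a quasi steady state by the endpoint —
with multiplicative Gaussian noise; real TXTL resource dynamics and growth
physiology are not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .plate import PlateSeries
from .seqcore import BarcodeGene, SequenceRecord

_BASES = np.array(list("ACGU"))


class SynthError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class GeneFamilySpec:
    """A root sequence plus per-species mutated homologs for each marker.

    Species ``sp00`` is the unmutated reference (the design target); the
    remaining ``n_species - 1`` species mutate i.i.d. per site at
    ``per_site_substitution_rate``.  ``planted_matches`` maps species name ->
    markers whose [pinned_window_start, +pinned_window_len) slice is forced
    back to the root sequence (pinning wins over mutation, with a warning).
    """

    n_species: int = 12
    markers: tuple[str, ...] = ("MatK", "RbcL", "TrnL-UAA")
    gene_length: int = 300
    per_site_substitution_rate: float = 0.1
    seed: int = 0
    planted_matches: Optional[Mapping[str, Sequence[str]]] = None
    pinned_window_start: int = 0
    pinned_window_len: int = 35

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_site_substitution_rate <= 1.0:
            raise SynthError("per_site_substitution_rate must be in [0, 1]")
        if self.n_species < 1:
            raise SynthError("need at least one species")
        if self.pinned_window_start + self.pinned_window_len > self.gene_length:
            raise SynthError("pinned window exceeds gene length")


@dataclass(frozen=True)
class GeneFamily:
    """Generated genes plus exact mutation ground truth."""

    spec: GeneFamilySpec
    roots: Mapping[str, str]                      # marker -> root sequence
    genes: tuple[BarcodeGene, ...]
    mutated: Mapping[tuple[str, str], np.ndarray]  # (species, marker) -> bool mask

    @property
    def species_names(self) -> list[str]:
        return list(dict.fromkeys(g.species for g in self.genes))

    def gene(self, species: str, marker: str) -> BarcodeGene:
        for g in self.genes:
            if g.species == species and g.marker == marker:
                return g
        raise KeyError((species, marker))

    def window_mismatches(
        self, species: str, marker: str, start: int, width: int = 35
    ) -> int:
        """True mismatch count of a [start, start+width) window vs the root."""
        mask = self.mutated[(species, marker)]
        return int(mask[start : start + width].sum())


def synth_gene_family(spec: GeneFamilySpec) -> GeneFamily:
    """Generate the panel; reproducible for a given (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    roots: dict[str, str] = {}
    genes: list[BarcodeGene] = []
    mutated: dict[tuple[str, str], np.ndarray] = {}
    planted = {k: set(v) for k, v in (spec.planted_matches or {}).items()}
    lo, hi = spec.pinned_window_start, spec.pinned_window_start + spec.pinned_window_len

    for marker in spec.markers:
        root_idx = rng.integers(0, 4, size=spec.gene_length)
        roots[marker] = "".join(_BASES[root_idx])

    for sp_i in range(spec.n_species):
        species = f"sp{sp_i:02d}"
        for marker in spec.markers:
            root_idx = np.array([_BASES.tolist().index(b) for b in roots[marker]])
            if sp_i == 0:
                mut = np.zeros(spec.gene_length, dtype=bool)
                seq = roots[marker]
            else:
                mut = rng.random(spec.gene_length) < spec.per_site_substitution_rate
                # uniform over the 3 alternative bases
                shift = rng.integers(1, 4, size=spec.gene_length)
                new_idx = np.where(mut, (root_idx + shift) % 4, root_idx)
                if marker in planted.get(species, ()):
                    if mut[lo:hi].any():
                        warnings.warn(
                            f"{species}/{marker}: {int(mut[lo:hi].sum())} mutations in "
                            "the pinned window reverted (pinning takes precedence)",
                            stacklevel=2,
                        )
                    new_idx[lo:hi] = root_idx[lo:hi]
                    mut[lo:hi] = False
                seq = "".join(_BASES[new_idx])
            rec = SequenceRecord(
                id=f"{species}_{marker}",
                residues=seq,
                description=f"synthetic {marker} homolog, species {species}",
            )
            genes.append(BarcodeGene(species, marker, rec))
            mutated[(species, marker)] = mut
    return GeneFamily(spec=spec, roots=roots, genes=tuple(genes), mutated=mutated)


@dataclass(frozen=True)
class GrowthSpec:
    """Logistic OD600 curve for in vivo mode."""

    od_max: float = 1.2
    t_mid: float = 300.0   # minutes
    scale: float = 60.0    # minutes


@dataclass(frozen=True)
class KineticsSpec:
    """Saturating-exponential reporter kinetics with a known true fold change.

    Mean trace: baseline + A * (1 - exp(-t / tau)) with tau =
    saturation_time / 3 (so the signal is ~95% saturated at
    ``saturation_time``); the ON-arm amplitude is ``true_fold_change`` times
    the OFF-arm amplitude ``off_amplitude``.  Noise is multiplicative
    Gaussian at ``noise_cv``.  ``baseline`` is the blank the plate pipeline
    subtracts during calibration.
    """

    true_fold_change: float = 60.0
    baseline: float = 50.0
    off_amplitude: float = 200.0
    saturation_time: float = 120.0
    noise_cv: float = 0.1
    sampling_interval: float = 5.0
    duration: float = 480.0
    n_replicates: int = 3
    seed: int = 0
    system: str = "cell_free"
    switch_id: str = "switch"
    growth: Optional[GrowthSpec] = None

    def __post_init__(self) -> None:
        if self.true_fold_change <= 0:
            raise SynthError("true_fold_change must be positive")
        if self.duration < self.sampling_interval:
            raise SynthError("duration shorter than the sampling interval")
        if not 0.0 <= self.noise_cv <= 1.0:
            raise SynthError("noise_cv must be in [0, 1]")
        if self.n_replicates < 1:
            raise SynthError("need at least one replicate")


def synth_plate_kinetics(spec: KineticsSpec, arm: str) -> list[PlateSeries]:
    """Generate replicate traces for one arm ("ON" with trigger, "OFF" without)."""
    if arm not in ("ON", "OFF"):
        raise SynthError(f"arm must be 'ON' or 'OFF', got {arm!r}")
    rng = np.random.default_rng([spec.seed, 0 if arm == "OFF" else 1])
    t = np.arange(0.0, spec.duration + 1e-9, spec.sampling_interval)
    tau = spec.saturation_time / 3.0
    amplitude = spec.off_amplitude * (spec.true_fold_change if arm == "ON" else 1.0)
    mean = spec.baseline + amplitude * (1.0 - np.exp(-t / tau))
    out = []
    for rep in range(1, spec.n_replicates + 1):
        noise = 1.0 + spec.noise_cv * rng.standard_normal(len(t))
        values = np.clip(mean * noise, 0.0, None)
        od = None
        if spec.growth is not None:
            g = spec.growth
            od = g.od_max / (1.0 + np.exp(-(t - g.t_mid) / g.scale))
        out.append(
            PlateSeries(
                well=f"{spec.switch_id}_{arm}_{rep}",
                switch_id=spec.switch_id,
                trigger_id=spec.switch_id + "_trigger" if arm == "ON" else "none",
                system=spec.system,
                replicate=rep,
                time=t,
                fluorescence=values,
                od600=od,
            )
        )
    return out
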