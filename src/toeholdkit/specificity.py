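"""Cross-species screening of toehold switches against a barcode-gene panel.

For each sensor, homologous trigger variants are pulled from every species in
the panel, their mismatches against the cognate binding site profiled, the
sensor-variant complex energy classified into strong / indeterminate /
nonfunctional bands, and a species-level call made by requiring an ON
response on all configured markers simultaneously (the conjunction rule of
multi-marker DNA barcoding).

The default energy cutoffs (-103 and -90 kcal/mol) mirror the published
ON/OFF-ratio boundaries they were derived from (fold change > 60 below the
strong cutoff, nonfunctional above the weak one); because any folding engine
assigns its own absolute energies, they are configuration values that can be
refit on labeled pairs with :func:`calibrate_thresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import design, rnafold
from .seqcore import BarcodeGene, hamming_mismatches


class SpecificityError(ValueError):
    """Invalid panel, window, or classifier input."""


ENERGY_CLASSES = ("strong", "indeterminate", "nonfunctional")


@dataclass(frozen=True)
class ClassifierConfig:
    """Energy and fold-change thresholds for the pair classifier.

    ``strong_cutoff`` (strict less-than) marks complexes expected to give
    large ON/OFF ratios; ``nonfunctional_cutoff`` (strict greater-than) marks
    non-binders; the band between has mixed behaviour and is resolved by the
    predicted bound fraction.  Units: kcal/mol.
    """

    strong_cutoff: float = -103.0
    nonfunctional_cutoff: float = -90.0
    strong_min_fold_change: float = 60.0
    on_call_fold_change: float = 10.0
    bound_fraction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.strong_cutoff) and math.isfinite(self.nonfunctional_cutoff)):
            raise SpecificityError("energy cutoffs must be finite")
        if self.strong_cutoff >= self.nonfunctional_cutoff:
            raise SpecificityError("strong_cutoff must lie below nonfunctional_cutoff")
        if self.strong_min_fold_change <= 1 or self.on_call_fold_change <= 1:
            raise SpecificityError("fold-change constants must exceed 1")


@dataclass
class PairClassification:
    """One sensor x trigger-variant row of the specificity matrix."""

    sensor_id: str
    species: str
    marker: str
    mismatch_count: int
    mismatch_positions: list[int]
    delta_g: float
    delta_delta_g: float
    bound_fraction: float
    energy_class: str = ""
    predicted_on: Optional[bool] = None
    rationale: str = ""


@dataclass(frozen=True)
class ConjunctionVerdict:
    """Species-level call: ON on every required marker simultaneously."""

    species: str
    per_marker_on: Mapping[str, bool]
    call: bool
    error: str = ""


def extract_variant_window(
    ref_window: design.TriggerWindow,
    other: BarcodeGene,
    mode: str = "coordinate",
) -> design.TriggerWindow:
    """The homologous trigger window in another species' gene.

    ``coordinate`` (default, for aligned barcode loci) takes the same
    [start, start+35) slice; ``best-match`` scans every window exhaustively
    and returns the minimal-mismatch one (ties to the smallest start).
    """
    width = ref_window.length
    if len(other) < width:
        raise SpecificityError(
            f"{other.species}/{other.marker} shorter than the {width}-nt window"
        )
    if mode == "coordinate":
        start = ref_window.start
        if start + width > len(other):
            raise SpecificityError(
                f"coordinate mode: window [{start}, {start + width}) out of range for "
                f"{other.species}/{other.marker} of length {len(other)}"
            )
        return design.TriggerWindow(other, start, other.sequence[start : start + width])
    if mode == "best-match":
        best = None
        for start in range(len(other) - width + 1):
            count, _ = hamming_mismatches(
                ref_window.sequence, other.sequence[start : start + width]
            )
            if best is None or count < best[0]:
                best = (count, start)
        start = best[1]
        return design.TriggerWindow(other, start, other.sequence[start : start + width])
    raise SpecificityError(f"unknown extraction mode {mode!r}")


def mismatch_profile(
    ref: design.TriggerWindow, var: design.TriggerWindow
) -> tuple[int, list[int]]:
    """Mismatch count and 0-based positions between cognate and variant windows."""
    return hamming_mismatches(ref.sequence, var.sequence)


def classify_pair_energy(delta_g: float, cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Band a complex energy: strong / indeterminate / nonfunctional.

    Boundary values fall in the adjacent non-strong class (strict < for
    strong, strict > for nonfunctional).
    """
    if math.isnan(delta_g):
        raise SpecificityError("delta_g is NaN")
    if delta_g < cfg.strong_cutoff:
        return "strong"
    if delta_g > cfg.nonfunctional_cutoff:
        return "nonfunctional"
    return "indeterminate"


def predict_pair_on(
    pc: PairClassification, cfg: ClassifierConfig = ClassifierConfig()
) -> tuple[bool, str]:
    """ON/OFF prediction for one pair, with the clause that fired.

    Strong pairs are ON; nonfunctional pairs are OFF regardless of bound
    fraction; indeterminate pairs are ON only when the predicted bound
    fraction reaches the configured threshold.
    """
    if pc.energy_class == "strong":
        return True, f"energy class strong (dG {pc.delta_g:.1f} < {cfg.strong_cutoff})"
    if pc.energy_class == "nonfunctional":
        return False, (
            f"energy class nonfunctional (dG {pc.delta_g:.1f} > "
            f"{cfg.nonfunctional_cutoff}); bound fraction ignored"
        )
    if pc.energy_class == "indeterminate":
        if pc.bound_fraction >= cfg.bound_fraction_threshold:
            return True, (
                f"indeterminate band, bound fraction {pc.bound_fraction:.2f} >= "
                f"{cfg.bound_fraction_threshold}"
            )
        return False, (
            f"indeterminate band, bound fraction {pc.bound_fraction:.2f} < "
            f"{cfg.bound_fraction_threshold}"
        )
    raise SpecificityError(f"unknown energy class {pc.energy_class!r}")


def conjunction_call(
    per_marker: Mapping[str, bool], required_markers: Sequence[str]
) -> ConjunctionVerdict:
    """AND over the required markers; a missing marker is an error, not False."""
    missing = [m for m in required_markers if m not in per_marker]
    if missing:
        raise SpecificityError(f"missing marker(s) in conjunction call: {missing}")
    call = all(per_marker[m] for m in required_markers)
    species = ""
    return ConjunctionVerdict(
        species=species,
        per_marker_on={m: bool(per_marker[m]) for m in required_markers},
        call=call,
    )


def specificity_matrix(
    sensors: Sequence[design.ToeholdSwitch],
    panel: Sequence[BarcodeGene],
    cfg: ClassifierConfig = ClassifierConfig(),
    model: rnafold.EnergyModel = rnafold.DEFAULT_MODEL,
    mode: str = "coordinate",
    trigger_len: int = 120,
    required_markers: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, list[ConjunctionVerdict]]:
    """Screen every sensor against every panel species of its marker.

    Returns a long-format table (one row per sensor x species) and the
    per-species conjunction verdicts.  A marker counts as ON for a species
    when any of its sensors is predicted ON against that species' variant
    trigger; species lacking a required marker get a recorded verdict error.
    """
    if not panel:
        raise SpecificityError("empty panel")
    if required_markers is None:
        required_markers = sorted({sw.window.gene.marker for sw in sensors})
    by_key = {(g.species, g.marker): g for g in panel}
    species_order = list(dict.fromkeys(g.species for g in panel))

    rows: list[PairClassification] = []
    for sw in sensors:
        marker = sw.window.gene.marker
        for species in species_order:
            gene = by_key.get((species, marker))
            if gene is None:
                continue
            var = extract_variant_window(sw.window, gene, mode)
            count, positions = mismatch_profile(sw.window, var)
            trig = design.build_trigger(gene, var, trigger_len)
            dup = rnafold.duplex_delta_g(sw.full_sequence, trig.sequence, model)
            pc = PairClassification(
                sensor_id=sw.id,
                species=species,
                marker=marker,
                mismatch_count=count,
                mismatch_positions=positions,
                delta_g=dup.delta_g_complex,
                delta_delta_g=dup.delta_delta_g,
                bound_fraction=dup.bound_fraction,
            )
            pc.energy_class = classify_pair_energy(pc.delta_g, cfg)
            pc.predicted_on, pc.rationale = predict_pair_on(pc, cfg)
            rows.append(pc)

    table = pd.DataFrame(
        {
            "sensor_id": [r.sensor_id for r in rows],
            "species": [r.species for r in rows],
            "marker": [r.marker for r in rows],
            "mismatch_count": [r.mismatch_count for r in rows],
            "mismatch_positions": [
                ";".join(map(str, r.mismatch_positions)) for r in rows
            ],
            "delta_g": [r.delta_g for r in rows],
            "delta_delta_g": [r.delta_delta_g for r in rows],
            "bound_fraction": [r.bound_fraction for r in rows],
            "energy_class": [r.energy_class for r in rows],
            "predicted_on": [r.predicted_on for r in rows],
            "rationale": [r.rationale for r in rows],
        }
    )

    verdicts: list[ConjunctionVerdict] = []
    for species in species_order:
        per_marker: dict[str, bool] = {}
        for marker in required_markers:
            hits = [
                r.predicted_on
                for r in rows
                if r.species == species and r.marker == marker
            ]
            if hits:
                per_marker[marker] = any(hits)
        try:
            verdict = conjunction_call(per_marker, required_markers)
            verdicts.append(
                ConjunctionVerdict(species, verdict.per_marker_on, verdict.call)
            )
        except SpecificityError as exc:
            verdicts.append(ConjunctionVerdict(species, per_marker, False, error=str(exc)))
    return table, verdicts


def empirical_on_call(
    fold_change: float, cfg: ClassifierConfig = ClassifierConfig()
) -> bool:
    """Convert a measured ON/OFF fold change into a boolean ON call."""
    if math.isnan(fold_change):
        raise SpecificityError("fold change is NaN")
    return fold_change >= cfg.on_call_fold_change


def calibrate_thresholds(
    delta_gs: Sequence[float],
    labels: Sequence[str],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassifierConfig:
    """Refit the two energy cutoffs on user-labeled pairs.

    ``labels`` are "strong" / "nonfunctional" (others ignored).  The strong
    cutoff is placed just above the highest strong energy and the
    nonfunctional cutoff just below the lowest nonfunctional energy, i.e. the
    widest band consistent with perfectly separable labels; overlapping
    labels fall back to the midpoint split that maximizes class purity.
    """
    strong = sorted(g for g, l in zip(delta_gs, labels) if l == "strong")
    nonf = sorted(g for g, l in zip(delta_gs, labels) if l == "nonfunctional")
    if not strong or not nonf:
        raise SpecificityError("need at least one pair of each label to calibrate")
    eps = 1e-6
    if strong[-1] < nonf[0]:
        lo, hi = strong[-1] + eps, nonf[0] - eps
    else:
        mid = 0.5 * (np.median(strong) + np.median(nonf))
        lo = hi = None
        best = -1
        for cut in sorted(set(delta_gs)):
            purity = sum(g <= cut for g in strong) + sum(g > cut for g in nonf)
            if purity > best:
                best, lo, hi = purity, cut + eps, cut + 2 * eps
        if lo is None:
            lo, hi = mid, mid + eps
    return ClassifierConfig(
        strong_cutoff=lo,
        nonfunctional_cutoff=max(hi, lo + eps),
        strong_min_fold_change=cfg.strong_min_fold_change,
        on_call_fold_change=cfg.on_call_fold_change,
        bound_fraction_threshold=cfg.bound_fraction_threshold,
    )
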