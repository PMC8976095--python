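"""Toehold-switch candidate generation, constraint checking, scoring, ranking.

A switch mRNA is assembled 5'->3' as::

    [ sensing region (35 nt) | loop with RBS | descending stem | AUG bulge |
      descending stem (cont.) | linker ]

The 35-nt sensing region is the reverse complement of a trigger window on the
barcode gene: its 5' 12 nt form the single-stranded toehold, the remaining
23 nt the ascending stem arm.  The descending stem re-pairs part of that arm
around an unpaired AUG bulge, sequestering the RBS and start codon until a
trigger strand invades through the toehold.

All architecture sequences shipped here (loop, linker) are package defaults
in the style of the published series-B toehold lineage, configurable via
YAML; they are design parameters, not measured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import rnafold
from .seqcore import (
    BarcodeGene,
    SequenceError,
    SequenceRecord,
    gc_fraction,
    max_homopolymer_run,
    reverse_complement,
    sliding_windows,
)

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


class DesignError(ValueError):
    """Invalid architecture configuration or scoring request."""


@dataclass(frozen=True)
class SwitchArchitecture:
    """Geometry and fixed sequences of the switch scaffold.

    The stem arm (sensing_len - toehold_len nt) pairs back against the
    descending stem in two segments: ``pre_start_stem_len`` base pairs between
    loop and AUG, ``post_start_stem_len`` base pairs after the AUG bulge; any
    remainder at the stem bottom stays unpaired.
    """

    sensing_len: int = 35
    toehold_len: int = 12
    loop_seq: str = "AACAGAGGAGA"        # contains the RBS motif
    rbs_motif: str = "AGGAGA"
    start_codon: str = "AUG"
    pre_start_stem_len: int = 9
    post_start_stem_len: int = 11
    linker_seq: str = "AACCUGGCGGCAGCGCAAAAG"  # 21 nt, common flexible linker
    gc_bounds: tuple[float, float] = (0.2, 0.8)
    max_homopolymer: int = 6

    def __post_init__(self) -> None:
        if self.toehold_len >= self.sensing_len:
            raise DesignError("toehold_len must be smaller than sensing_len")
        if self.stem_bottom_unpaired < 0:
            raise DesignError(
                "pre_start_stem_len + post_start_stem_len exceeds the stem arm length"
            )
        if self.rbs_motif not in self.loop_seq:
            raise DesignError(
                f"loop_seq {self.loop_seq!r} does not contain the RBS motif "
                f"{self.rbs_motif!r}"
            )
        if len(self.linker_seq) % 3 != 0:
            raise DesignError("linker_seq length must be a multiple of 3")

    @property
    def stem_arm_len(self) -> int:
        return self.sensing_len - self.toehold_len

    @property
    def stem_bottom_unpaired(self) -> int:
        return self.stem_arm_len - self.pre_start_stem_len - self.post_start_stem_len

    @property
    def aug_offset(self) -> int:
        """0-based position of the start codon in the full switch sequence."""
        return self.sensing_len + len(self.loop_seq) + self.pre_start_stem_len

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SwitchArchitecture":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gc_bounds" in raw:
            raw["gc_bounds"] = tuple(raw["gc_bounds"])
        return cls(**raw)


@dataclass(frozen=True)
class TriggerWindow:
    """A 35-nt (by default) window on a barcode gene: the trigger binding site."""

    gene: BarcodeGene
    start: int
    sequence: str

    def __post_init__(self) -> None:
        expected = self.gene.sequence[self.start : self.start + len(self.sequence)]
        if self.sequence != expected:
            raise DesignError(
                f"window sequence does not match {self.gene.species}/{self.gene.marker}"
                f"[{self.start}:{self.start + len(self.sequence)}]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ToeholdSwitch:
    """An assembled switch candidate with its designed hairpin and scores."""

    id: str
    window: TriggerWindow
    sensing_region: str
    full_sequence: str
    designed_structure: str
    score: float = float("nan")
    score_components: dict = field(default_factory=dict)
    rank: int = 0


@dataclass(frozen=True)
class TriggerConstruct:
    """The synthesized trigger RNA: a gene fragment containing the binding site."""

    sequence: str
    binding_site_offset: int
    window: TriggerWindow
    truncated: bool = False

    def __post_init__(self) -> None:
        site = self.sequence[
            self.binding_site_offset : self.binding_site_offset + self.window.length
        ]
        if site != self.window.sequence:
            raise DesignError("trigger construct does not contain the binding site")


@dataclass(frozen=True)
class ScoreWeights:
    """Composite-score weights (package defaults; always reported alongside scores)."""

    hairpin_fidelity: float = 0.4
    toehold_accessibility: float = 0.3
    activation: float = 0.3
    activation_scale: float = 30.0  # kcal/mol of hybridization gain mapped to score 1.0


def build_switch(window: TriggerWindow, arch: SwitchArchitecture) -> ToeholdSwitch:
    """Assemble the full switch mRNA and its designed dot-bracket for a window."""
    if window.length != arch.sensing_len:
        raise DesignError(
            f"window length {window.length} != architecture sensing_len {arch.sensing_len}"
        )
    s = reverse_complement(window.sequence)
    arm_lo = arch.toehold_len + arch.stem_bottom_unpaired
    seg_a = s[arm_lo : arm_lo + arch.post_start_stem_len]       # outer stem arm
    seg_b = s[arm_lo + arch.post_start_stem_len :]              # inner arm, abuts loop
    assert len(seg_b) == arch.pre_start_stem_len
    full = (
        s
        + arch.loop_seq
        + reverse_complement(seg_b)
        + arch.start_codon
        + reverse_complement(seg_a)
        + arch.linker_seq
    )
    structure = (
        "." * (arch.toehold_len + arch.stem_bottom_unpaired)
        + "(" * (arch.pre_start_stem_len + arch.post_start_stem_len)
        + "." * len(arch.loop_seq)
        + ")" * arch.pre_start_stem_len
        + "." * len(arch.start_codon)
        + ")" * arch.post_start_stem_len
        + "." * len(arch.linker_seq)
    )
    assert len(structure) == len(full)
    switch_id = f"{window.gene.species}_{window.gene.marker}_w{window.start}"
    return ToeholdSwitch(
        id=switch_id,
        window=window,
        sensing_region=s,
        full_sequence=full,
        designed_structure=structure,
    )


def check_constraints(
    sw: ToeholdSwitch, arch: SwitchArchitecture, strict: bool = False
) -> tuple[bool, list[str]]:
    """Validate an assembled switch; returns (passed, reasons).

    Hard failures: a stop codon in frame with the AUG anywhere before the
    linker end, or a displaced start codon.  GC-content and homopolymer
    bounds are soft (reported, enforced only with ``strict=True``).
    """
    reasons: list[str] = []
    hard: list[str] = []
    aug = arch.aug_offset
    if sw.full_sequence[aug : aug + 3] != arch.start_codon:
        hard.append(f"start codon displaced from offset {aug}")
    orf = sw.full_sequence[aug:]
    for off in range(3, len(orf) - 2, 3):
        codon = orf[off : off + 3]
        if codon in STOP_CODONS:
            hard.append(f"in-frame stop {codon} at switch position {aug + off}")
            break
    gc = gc_fraction(sw.sensing_region)
    lo, hi = arch.gc_bounds
    if not lo <= gc <= hi:
        reasons.append(f"sensing-region GC {gc:.2f} outside [{lo}, {hi}]")
    run = max_homopolymer_run(sw.full_sequence)
    if run > arch.max_homopolymer:
        reasons.append(f"homopolymer run of {run} exceeds {arch.max_homopolymer}")
    passed = not hard and (not strict or not reasons)
    return passed, hard + reasons


def score_candidate(
    sw: ToeholdSwitch,
    source_context: SequenceRecord | str,
    model: rnafold.EnergyModel = rnafold.DEFAULT_MODEL,
    weights: ScoreWeights = ScoreWeights(),
    arch: SwitchArchitecture = SwitchArchitecture(),
) -> ToeholdSwitch:
    """Attach score components and the composite score (higher is better).

    Components: hairpin fidelity (fraction of designed stem pairs recovered in
    the MFE fold of the full switch), toehold accessibility (fraction of
    window positions unpaired in the MFE fold of the source context), and an
    activation term (sensor-trigger hybridization gain -ddG scaled to [0, 1]).
    """
    passed, reasons = check_constraints(sw, arch)
    if not passed:
        raise DesignError(f"refusing to score constraint-failing switch: {reasons}")
    context = (
        source_context.residues
        if isinstance(source_context, SequenceRecord)
        else source_context
    )
    designed_pairs = set(
        rnafold.validate_dotbracket(sw.designed_structure, sw.full_sequence)
    )
    mfe_switch = rnafold.fold_mfe(sw.full_sequence, model)
    fidelity = (
        len(designed_pairs & set(mfe_switch.pairs)) / len(designed_pairs)
        if designed_pairs
        else 1.0
    )

    pos = context.find(sw.window.sequence)
    if pos < 0:
        raise DesignError("trigger window not found in the supplied source context")
    mfe_ctx = rnafold.fold_mfe(context, model)
    paired = {i for p in mfe_ctx.pairs for i in p}
    win_positions = range(pos, pos + sw.window.length)
    accessibility = sum(1 for i in win_positions if i not in paired) / sw.window.length

    dup = rnafold.duplex_delta_g(sw.full_sequence, sw.window.sequence, model)
    activation = min(1.0, max(0.0, -dup.delta_delta_g / weights.activation_scale))

    sw.score_components = {
        "hairpin_fidelity": fidelity,
        "toehold_accessibility": accessibility,
        "activation": activation,
        "delta_delta_g": dup.delta_delta_g,
        "switch_mfe": mfe_switch.energy,
        "weights": (
            weights.hairpin_fidelity,
            weights.toehold_accessibility,
            weights.activation,
        ),
    }
    sw.score = (
        weights.hairpin_fidelity * fidelity
        + weights.toehold_accessibility * accessibility
        + weights.activation * activation
    )
    return sw


def enumerate_candidates(
    gene: BarcodeGene,
    arch: SwitchArchitecture = SwitchArchitecture(),
    step: int = 1,
    model: rnafold.EnergyModel = rnafold.DEFAULT_MODEL,
    weights: ScoreWeights = ScoreWeights(),
    strict: bool = False,
    score: bool = True,
) -> list[ToeholdSwitch]:
    """One scored candidate per constraint-passing trigger window of the gene.

    Windows are scanned on the plus strand at the given step.  Scoring uses
    the whole gene as the source context for toehold accessibility.
    """
    if len(gene) < arch.sensing_len:
        warnings.warn(
            f"gene {gene.species}/{gene.marker} shorter than sensing_len; no candidates",
            stacklevel=2,
        )
        return []
    out: list[ToeholdSwitch] = []
    for start, subseq in sliding_windows(gene.sequence, arch.sensing_len, step):
        window = TriggerWindow(gene, start, subseq)
        sw = build_switch(window, arch)
        passed, reasons = check_constraints(sw, arch, strict)
        if not passed:
            continue
        if score:
            score_candidate(sw, gene.record, model, weights, arch)
        out.append(sw)
    return out


def rank_and_select(cands: Sequence[ToeholdSwitch], top_k: int) -> list[ToeholdSwitch]:
    """Top-k by descending composite score; ties broken by smaller window start."""
    if top_k < 1:
        raise DesignError(f"top_k must be >= 1, got {top_k}")
    ranked = sorted(cands, key=lambda sw: (-sw.score, sw.window.start))
    selected = ranked[:top_k]
    for rank, sw in enumerate(selected, start=1):
        sw.rank = rank
    return selected


def build_trigger(
    gene: BarcodeGene,
    window: TriggerWindow,
    trigger_len: int = 120,
    offset: Optional[int] = None,
) -> TriggerConstruct:
    """Cut a trigger fragment of the gene containing the binding-site window.

    Default placement centers the binding site in the fragment, clipping at
    the gene ends; ``offset`` forces an explicit binding-site offset instead.
    A gene shorter than ``trigger_len`` is returned whole, flagged truncated.
    """
    if window.gene is not gene and window.gene.sequence != gene.sequence:
        raise DesignError("window does not belong to the supplied gene")
    L = len(gene)
    if L < trigger_len:
        warnings.warn(
            f"gene length {L} < trigger length {trigger_len}; returning whole gene",
            stacklevel=2,
        )
        return TriggerConstruct(gene.sequence, window.start, window, truncated=True)
    if offset is not None:
        start = window.start - offset
        if start < 0 or start + trigger_len > L:
            raise DesignError(
                f"explicit offset {offset} places the trigger outside the gene"
            )
    else:
        start = window.start + window.length // 2 - trigger_len // 2
        start = min(max(start, 0), L - trigger_len)
    return TriggerConstruct(
        sequence=gene.sequence[start : start + trigger_len],
        binding_site_offset=window.start - start,
        window=window,
    )
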