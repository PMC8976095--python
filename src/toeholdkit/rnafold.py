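"""Self-contained RNA thermodynamics.

Single-strand minimum-free-energy folding by dynamic programming over nested
structures, an exhaustive brute-force oracle for short sequences, two-strand
(sensor-trigger) complex folding via the standard linker-concatenation trick,
and a two-state estimate of the fraction of trigger bound.

Energy model
------------
A structure's free energy is the sum of (i) a per-pair formation term and
(ii) a stacking term for every pair (i, j) whose inner neighbour (i+1, j-1)
is also paired.  The shipped default ("turner-stack-v1") uses a Turner-style
stacking table with zero per-pair terms; a "unit-pair" model (-1 kcal/mol per
pair, no stacking) is provided for oracle tests.  Pairs are Watson-Crick or
G.U wobble; hairpin loops must enclose at least ``min_hairpin_loop`` unpaired
bases; no dangles, no coaxial stacking, no pseudoknots.

All energies are handled internally in integer centi-kcal/mol so that
co-optimal tie-breaking is exact.  Among co-optimal structures the canonical
one minimizes (energy, number of pairs, sorted pair list) lexicographically;
both the DP traceback and the brute-force oracle implement this same rule, so
they agree structure-for-structure, not just in energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .seqcore import CANONICAL, SequenceError

R_KCAL = 0.0019872  # kcal / (mol K)

_PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
_WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
_GU_PAIRS = frozenset({"GU", "UG"})

# key = energy_centikcal * _SHIFT + n_pairs: lexicographic (E, P) order as a
# single additive integer (valid while n_pairs < _SHIFT).
_SHIFT = 1024
_INF = 1 << 50


class FoldError(ValueError):
    """Invalid folding input (bad residue, empty sequence, oversize oracle call)."""


def _swap(pair: str) -> str:
    return pair[1] + pair[0]


@dataclass(frozen=True)
class EnergyModel:
    """Thermodynamic parameters for folding.

    ``pair_energies`` maps pair type ("AU", "GC", ...) to a formation energy in
    kcal/mol; ``stack_table`` maps (outer, inner) pair-type tuples to stacking
    energies.  Stacking entries must be <= 0 (a bonus).  ``temperature`` is in
    kelvin; the default 310.15 K gives RT = 0.6163 kcal/mol.
    """

    model_name: str
    temperature: float = 310.15
    min_hairpin_loop: int = 3
    pair_energies: dict[str, float] = field(default_factory=dict)
    stack_table: Optional[dict[tuple[str, str], float]] = None
    allow_gu: bool = True

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.stack_table is not None:
            for key, val in self.stack_table.items():
                if not math.isfinite(val):
                    raise ValueError(f"non-finite stack energy for {key}")
                if val > 0:
                    raise ValueError(f"positive stack energy for {key}; clip to 0")

    @property
    def RT(self) -> float:
        """kcal/mol."""
        return R_KCAL * self.temperature

    @property
    def allowed_pairs(self) -> frozenset[str]:
        return _WC_PAIRS | _GU_PAIRS if self.allow_gu else _WC_PAIRS

    @classmethod
    def unit(cls, pair_energy: float = -1.0, allow_gu: bool = True) -> "EnergyModel":
        """Flat -1 kcal/mol per pair, no stacking: the oracle-test model."""
        pairs = _PAIR_TYPES if allow_gu else tuple(_WC_PAIRS)
        return cls(
            model_name="unit-pair",
            pair_energies={p: pair_energy for p in pairs},
            allow_gu=allow_gu,
        )

    @classmethod
    def turner_stacking(cls) -> "EnergyModel":
        """The shipped nearest-neighbor stacking model (data/stack_params.yaml)."""
        text = resources.files("toeholdkit.data").joinpath("stack_params.yaml").read_text()
        raw = yaml.safe_load(text)
        stacks: dict[tuple[str, str], float] = {}
        for key, val in raw["stacks"].items():
            outer, inner = key.split("|")
            val = min(float(val), 0.0)
            mirror = (_swap(inner), _swap(outer))
            for k in ((outer, inner), mirror):
                if k in stacks and abs(stacks[k] - val) > 1e-9:
                    raise ValueError(f"conflicting stack entries for {k}")
                stacks[k] = val
        missing = [
            (a, b) for a in _PAIR_TYPES for b in _PAIR_TYPES if (a, b) not in stacks
        ]
        if missing:
            raise ValueError(f"stack table incomplete, missing {missing[:4]}...")
        return cls(
            model_name=raw["model_name"],
            min_hairpin_loop=int(raw["min_hairpin_loop"]),
            stack_table=stacks,
        )


DEFAULT_MODEL = EnergyModel.turner_stacking()


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its model energy (kcal/mol)."""

    sequence: str
    dotbracket: str
    energy: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return validate_dotbracket(self.dotbracket, self.sequence)


@dataclass(frozen=True)
class DuplexPrediction:
    """Sensor-trigger complex energetics.

    ``delta_g_complex`` is the MFE of the two-strand complex, ``delta_g_separate``
    the sum of the monomer MFEs, and ``delta_delta_g`` their difference (the
    hybridization gain, always <= 0).  ``pair_map`` lists intermolecular pairs
    as (sensor position, trigger position).
    """

    sensor: str
    trigger: str
    delta_g_complex: float
    delta_g_separate: float
    delta_delta_g: float
    bound_fraction: float
    pair_map: tuple[tuple[int, int], ...]
    complex_dotbracket: str = ""


def _check_rna(seq: str) -> None:
    if not seq:
        raise FoldError("empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in CANONICAL:
            raise FoldError(f"non-canonical residue {ch!r} at position {pos}")


def validate_dotbracket(db: str, seq: str | None = None) -> list[tuple[int, int]]:
    """Return the (i, j) pairs of a dot-bracket string; reject malformed input.

    With ``seq`` given, lengths must match and every pair must be Watson-Crick
    or G.U.
    """
    if seq is not None and len(seq) != len(db):
        raise ValueError(
            f"dot-bracket length {len(db)} does not match sequence length {len(seq)}"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at index {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at index {idx}")
    if stack:
        raise ValueError(f"unbalanced '(' at index {stack[0]}")
    pairs.sort()
    if seq is not None:
        for i, j in pairs:
            if seq[i] + seq[j] not in _WC_PAIRS | _GU_PAIRS:
                raise ValueError(
                    f"illegal pair {seq[i]}{seq[j]} at ({i}, {j}); not Watson-Crick/GU"
                )
    return pairs


def _pairs_to_dotbracket(pairs: Sequence[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def _centi(x: float) -> int:
    return int(round(100.0 * x))


class _Folder:
    """Shared DP machinery for single strands and concatenated dimers.

    ``blocked`` positions cannot pair (the dimer spacer).  A candidate pair
    that encloses the whole blocked region spans the strand break, so the
    minimum-hairpin-loop constraint is waived for it.
    """

    def __init__(
        self,
        seq: str,
        model: EnergyModel,
        blocked: frozenset[int] = frozenset(),
    ) -> None:
        _check_rna(seq)
        self.seq = seq
        self.model = model
        self.n = n = len(seq)
        self.blocked = blocked
        bmin = min(blocked) if blocked else None
        bmax = max(blocked) if blocked else None
        allowed = model.allowed_pairs
        pair_centi = {p: _centi(model.pair_energies.get(p, 0.0)) for p in _PAIR_TYPES}
        stack = model.stack_table
        self.stack_key = None
        self.ptype = ptype = np.full((n, n), -1, dtype=np.int8)
        self.pair_key = pk = np.full((n, n), _INF, dtype=np.int64)
        minloop = model.min_hairpin_loop
        for i in range(n):
            if i in blocked:
                continue
            for j in range(i + 1, n):
                if j in blocked:
                    continue
                p = seq[i] + seq[j]
                if p not in allowed:
                    continue
                spans_break = bmin is not None and i < bmin and j > bmax
                if j - i - 1 < minloop and not spans_break:
                    continue
                ptype[i, j] = _PAIR_TYPES.index(p)
                pk[i, j] = pair_centi[p] * _SHIFT + 1
        if stack is not None:
            sk = np.zeros((6, 6), dtype=np.int64)
            for a, pa in enumerate(_PAIR_TYPES):
                for b, pb in enumerate(_PAIR_TYPES):
                    sk[a, b] = _centi(stack[(pa, pb)]) * _SHIFT
            self.stack_key = sk
        self._run_dp()

    def _run_dp(self) -> None:
        n, pk = self.n, self.pair_key
        W = np.zeros((n, n), dtype=np.int64)
        V = np.full((n, n), _INF, dtype=np.int64)
        ptype, sk = self.ptype, self.stack_key
        for j in range(1, n):
            Wcol = W[:, j]
            for i in range(j - 1, -1, -1):
                if pk[i, j] < _INF:
                    interior = W[i + 1, j - 1] if i + 1 <= j - 1 else 0
                    best = interior
                    if (
                        sk is not None
                        and i + 1 <= j - 1
                        and V[i + 1, j - 1] < _INF
                    ):
                        stacked = V[i + 1, j - 1] + sk[ptype[i, j], ptype[i + 1, j - 1]]
                        if stacked < best:
                            best = stacked
                    V[i, j] = pk[i, j] + best
                # W recursion: i unpaired, or i paired to some k in (i, j]
                best_w = W[i + 1, j] if i + 1 <= j else 0
                row = V[i, i + 1 : j + 1]
                if row.size:
                    wnext = np.empty(row.size, dtype=np.int64)
                    wnext[:-1] = Wcol[i + 2 : j + 1]
                    wnext[-1] = 0
                    cand = int((row + wnext).min())
                    if cand < best_w:
                        best_w = cand
                W[i, j] = best_w
        self.W, self.V = W, V

    # -- canonical traceback: minimize (E, n_pairs, sorted pair list) --------

    def trace(self) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        self._trace_w(0, self.n - 1, pairs)
        return sorted(pairs)

    def _w(self, i: int, j: int) -> int:
        return int(self.W[i, j]) if i <= j else 0

    def _trace_w(self, i: int, j: int, out: list[tuple[int, int]]) -> None:
        while i < j:
            target = self._w(i, j)
            paired = False
            for k in range(i + 1, j + 1):
                if self.V[i, k] < _INF and self.V[i, k] + self._w(k + 1, j) == target:
                    self._trace_v(i, k, out)
                    i = k + 1
                    paired = True
                    break
            if not paired:
                assert self._w(i + 1, j) == target
                i += 1

    def _trace_v(self, i: int, j: int, out: list[tuple[int, int]]) -> None:
        out.append((i, j))
        if i + 1 > j - 1:
            return
        key = int(self.V[i, j])
        base = int(self.pair_key[i, j])
        if base + self._w(i + 1, j - 1) == key:
            # interior at its own optimum: greedy continuation is pairs-lex minimal
            self._trace_w(i + 1, j - 1, out)
        else:
            sk = self.stack_key[self.ptype[i, j], self.ptype[i + 1, j - 1]]
            assert base + int(self.V[i + 1, j - 1]) + int(sk) == key
            self._trace_v(i + 1, j - 1, out)

    @property
    def mfe_key(self) -> int:
        return self._w(0, self.n - 1)

    @property
    def mfe_energy(self) -> float:
        return (self.mfe_key // _SHIFT) / 100.0


def fold_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> SecondaryStructure:
    """Minimum-free-energy nested structure of a single strand.

    Deterministic: among co-optimal structures the canonical one (fewest
    pairs, then lexicographically smallest sorted pair list) is returned.
    """
    folder = _Folder(seq, model)
    pairs = folder.trace()
    return SecondaryStructure(seq, _pairs_to_dotbracket(pairs, len(seq)), folder.mfe_energy)


def structure_energy(
    seq: str,
    pairs: Sequence[tuple[int, int]],
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Energy of an explicit pair set under the model (pair + stacking terms)."""
    pairset = set(map(tuple, pairs))
    total = 0.0
    for i, j in pairset:
        p = seq[i] + seq[j]
        total += model.pair_energies.get(p, 0.0)
        if model.stack_table is not None and (i + 1, j - 1) in pairset:
            total += model.stack_table[(p, seq[i + 1] + seq[j - 1])]
    return round(total, 6)


_BRUTE_MAX = 16


def brute_force_fold(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    _blocked: frozenset[int] = frozenset(),
) -> SecondaryStructure:
    """Exhaustive enumeration of all nested, loop-legal structures (length <= 16).

    The global minimum is returned under the same (energy, n_pairs, pair list)
    tie-break as :func:`fold_mfe`; this is the test oracle.
    """
    _check_rna(seq)
    if len(seq) > _BRUTE_MAX:
        raise FoldError(
            f"brute_force_fold refuses length {len(seq)} > {_BRUTE_MAX} "
            "(combinatorial explosion guard)"
        )
    folder = _Folder(seq, model, _blocked)  # reuse the legality matrix only
    pk = folder.pair_key

    def enum(i: int, j: int):
        if i >= j:
            yield ()
            return
        yield from enum(i + 1, j)
        for k in range(i + 1, j + 1):
            if pk[i, k] < _INF:
                for inner in enum(i + 1, k - 1):
                    for outer in enum(k + 1, j):
                        yield ((i, k),) + inner + outer

    best_key = None
    best_pairs: tuple[tuple[int, int], ...] = ()
    for pairs in enum(0, len(seq) - 1):
        e = _centi(structure_energy(seq, pairs, model))
        key = (e, len(pairs), tuple(sorted(pairs)))
        if best_key is None or key < best_key:
            best_key = key
            best_pairs = tuple(sorted(pairs))
    energy = best_key[0] / 100.0
    return SecondaryStructure(seq, _pairs_to_dotbracket(best_pairs, len(seq)), energy)


_SPACER_LEN = 3


def duplex_delta_g(
    sensor: str,
    trigger: str,
    model: EnergyModel = DEFAULT_MODEL,
) -> DuplexPrediction:
    """Fold the sensor-trigger two-strand complex and report its energetics.

    The strands are concatenated with a 3-position non-pairing spacer; spacer
    positions are barred from pairing and pairs spanning the strand break are
    exempt from the hairpin-loop minimum.  ``delta_delta_g`` (complex minus
    separate monomers) is never positive: the complex can always reproduce the
    two monomer folds with no intermolecular pairs.
    """
    _check_rna(sensor)
    _check_rna(trigger)
    la = len(sensor)
    combined = sensor + "A" * _SPACER_LEN + trigger
    blocked = frozenset(range(la, la + _SPACER_LEN))
    folder = _Folder(combined, model, blocked)
    pairs = folder.trace()
    dg_complex = folder.mfe_energy
    dg_sep = fold_mfe(sensor, model).energy + fold_mfe(trigger, model).energy
    ddg = round(dg_complex - dg_sep, 6)
    inter = tuple(
        (i, j - la - _SPACER_LEN)
        for i, j in pairs
        if i < la and j >= la + _SPACER_LEN
    )
    db = _pairs_to_dotbracket(pairs, len(combined))
    db = db[:la] + "&" + db[la + _SPACER_LEN :]
    return DuplexPrediction(
        sensor=sensor,
        trigger=trigger,
        delta_g_complex=dg_complex,
        delta_g_separate=round(dg_sep, 6),
        delta_delta_g=ddg,
        bound_fraction=bound_fraction(ddg, model),
        pair_map=inter,
        complex_dotbracket=db,
    )


def bound_fraction(
    pred_or_ddg: DuplexPrediction | float,
    model: EnergyModel = DEFAULT_MODEL,
    concentration: float | None = None,
) -> float:
    """Two-state estimate of the fraction of trigger bound to the sensor.

    Default (concentration-free reference state): f = 1 / (1 + exp(ddG/RT)),
    so ddG = 0 gives exactly 0.5.  With ``concentration`` (mol/L, e.g. 2e-6
    for the 2 uM cell-free condition): K = exp(-ddG/RT), f = Kc / (1 + Kc).
    Clamped to [0, 1].
    """
    ddg = (
        pred_or_ddg.delta_delta_g
        if isinstance(pred_or_ddg, DuplexPrediction)
        else float(pred_or_ddg)
    )
    if math.isnan(ddg):
        raise ValueError("delta_delta_g is NaN")
    x = ddg / model.RT
    if concentration is None:
        if x > 500:
            return 0.0
        if x < -500:
            return 1.0
        return 1.0 / (1.0 + math.exp(x))
    if concentration <= 0:
        raise ValueError("concentration must be positive (mol/L)")
    logkc = -x + math.log(concentration)
    if logkc > 500:
        return 1.0
    kc = math.exp(logkc)
    return min(1.0, max(0.0, kc / (1.0 + kc)))


def write_dotbracket(structure: SecondaryStructure, path) -> None:
    """Write sequence + structure + energy comment as plain text."""
    with open(path, "w") as fh:
        fh.write(f"{structure.sequence}\n{structure.dotbracket}\n# {structure.energy:.2f} kcal/mol\n")


def read_dotbracket(path) -> SecondaryStructure:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    seq, db = lines[0], lines[1]
    energy = 0.0
    if len(lines) > 2 and lines[2].startswith("#"):
        energy = float(lines[2].lstrip("#").split()[0])
    validate_dotbracket(db, seq)
    return SecondaryStructure(seq, db, energy)
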