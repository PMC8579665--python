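"""Core metabolic-model container with exact rational stoichiometry."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

from ._linalg import Vec

Relation = str  # ">=" or "<="


def _as_frac_matrix(S) -> tuple[Vec, ...]:
    return tuple(tuple(Fraction(x) for x in row) for row in S)


@dataclass(frozen=True)
class MetabolicModel:
    """A named stoichiometric system ``S v = 0`` with reversibility flags.

    Rows of ``S`` are metabolites, columns are reactions.  ``rev[i]`` marks
    reaction i reversible; irreversible reactions carry flux >= 0.  Bounds
    ``lb``/``ub`` are optional exact rationals (None = unbounded); by
    convention fluxes are in mmol/gDW/h but units are not enforced.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: tuple[Vec, ...]
    rev: tuple[bool, ...]
    lb: tuple[Fraction | None, ...] = None  # type: ignore[assignment]
    ub: tuple[Fraction | None, ...] = None  # type: ignore[assignment]
    objective_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "S", _as_frac_matrix(self.S))
        object.__setattr__(self, "rev", tuple(bool(r) for r in self.rev))
        n = len(self.reaction_ids)
        lb = self.lb if self.lb is not None else (None,) * n
        ub = self.ub if self.ub is not None else (None,) * n
        object.__setattr__(
            self, "lb", tuple(None if x is None else Fraction(x) for x in lb)
        )
        object.__setattr__(
            self, "ub", tuple(None if x is None else Fraction(x) for x in ub)
        )
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n:
            raise ValueError("duplicate reaction ids")
        if any(not rid for rid in self.reaction_ids) or any(
            not mid for mid in self.metabolite_ids
        ):
            raise ValueError("empty id string")
        if len(self.S) != m or any(len(row) != n for row in self.S):
            raise ValueError(f"S must be {m}x{n}")
        if not (len(self.rev) == len(self.lb) == len(self.ub) == n):
            raise ValueError("rev/lb/ub length mismatch")
        for i in range(n):
            lo, hi = self.lb[i], self.ub[i]
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"lb > ub for reaction {self.reaction_ids[i]}")
            if not self.rev[i] and lo is not None and lo < 0:
                raise ValueError(
                    f"irreversible reaction {self.reaction_ids[i]} has lb < 0"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def column(self, j: int) -> Vec:
        return tuple(row[j] for row in self.S)

    def with_(self, **kw) -> "MetabolicModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class BoundsTable:
    """User-supplied flux bounds: (reaction_id, relation, value) rows.

    Relation is ``">="`` (lower bound) or ``"<="`` (upper bound).
    """

    entries: tuple[tuple[str, Relation, Fraction], ...] = field(default_factory=tuple)

    def __post_init__(self):
        norm = []
        for rid, rel, val in self.entries:
            if rel not in (">=", "<="):
                raise ValueError(f"relation must be '>=' or '<=', got {rel!r}")
            norm.append((rid, rel, Fraction(val)))
        object.__setattr__(self, "entries", tuple(norm))

    @classmethod
    def from_tsv(cls, path) -> "BoundsTable":
        entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 tab-separated fields"
                    )
                entries.append((parts[0], parts[1], Fraction(parts[2])))
        return cls(tuple(entries))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for rid, rel, val in self.entries:
                fh.write(f"{rid}\t{rel}\t{val}\n")
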