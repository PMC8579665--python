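"""Flux-mode containers and downstream analytics.

A :class:`FluxMode` is an exact rational vector over a named reaction
index, classified as ``efm`` (extreme ray, defined up to positive scaling,
stored gcd-normalized) or ``efv`` (extreme point, an actual flux vector
whose magnitudes are meaningful and must not be rescaled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

import numpy as np

from ._linalg import Vec, mode_sort_key, support_bits


def _normalize_ray(values: Sequence[Fraction]) -> Vec:
    """Positive-scale *values* to coprime integers (orientation preserved)."""
    den = 1
    for x in values:
        if x:
            den = den * x.denominator // gcd(den, x.denominator)
    ints = [int(x * den) for x in values]
    g = 0
    for v in ints:
        g = gcd(g, v)
    if g == 0:
        return tuple(Fraction(0) for _ in ints)
    return tuple(Fraction(v, g) for v in ints)


@dataclass(frozen=True)
class FluxMode:
    values: Vec
    kind: str  # "efm" | "efv"

    def __post_init__(self):
        if self.kind not in ("efm", "efv"):
            raise ValueError(f"kind must be 'efm' or 'efv', got {self.kind!r}")
        vals = tuple(Fraction(x) for x in self.values)
        if self.kind == "efm":
            vals = _normalize_ray(vals)
        object.__setattr__(self, "values", vals)

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, x in enumerate(self.values) if x)

    @property
    def support_bits(self) -> int:
        return support_bits(self.values)

    def sort_key(self):
        return (self.kind, mode_sort_key(self.values))


@dataclass(frozen=True)
class ModeSet:
    """Canonically sorted, duplicate-free collection of equal-length modes."""

    reaction_ids: tuple[str, ...]
    modes: tuple[FluxMode, ...]

    def __post_init__(self):
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        n = len(self.reaction_ids)
        for mode in self.modes:
            if len(mode.values) != n:
                raise ValueError("mode length does not match reaction namespace")
        ordered = tuple(sorted(set(self.modes), key=FluxMode.sort_key))
        object.__setattr__(self, "modes", ordered)

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def value_set(self) -> frozenset[tuple[str, Vec]]:
        return frozenset((m.kind, m.values) for m in self.modes)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path, decimal: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write("mode\tkind\t" + "\t".join(self.reaction_ids) + "\n")
            for i, mode in enumerate(self.modes):
                cells = [
                    f"{float(x):.10g}" if decimal else str(x) for x in mode.values
                ]
                fh.write(f"{i}\t{mode.kind}\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ModeSet":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["mode", "kind"]:
                raise ValueError(f"{path}: not a mode TSV (bad header)")
            rids = tuple(header[2:])
            modes = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(rids) + 2:
                    raise ValueError(f"{path}: row arity mismatch")
                modes.append(
                    FluxMode(tuple(Fraction(p) for p in parts[2:]), parts[1])
                )
        return cls(rids, tuple(modes))


# ---------------------------------------------------------------------------
# two-cycle removal and reversible-split merging


def filter_two_cycles(modes: ModeSet, record) -> ModeSet:
    """Drop the artifactual modes that cycle a single split reversible pair.

    A split reversible reaction contributes one spurious extreme ray whose
    support is exactly ``{forward, reverse}``; it carries no net flux and is
    not a biological pathway.  Genuine two-reaction cycles between distinct
    reactions are retained.
    """
    pair_supports = set()
    for fwd, bwd in record.split_pairs.values():
        if bwd is not None:
            pair_supports.add(frozenset((fwd, bwd)))
    kept = tuple(m for m in modes if m.support not in pair_supports)
    return ModeSet(modes.reaction_ids, kept)


def merge_split_pairs(modes: ModeSet, record, two_cycles: str = "error") -> ModeSet:
    """Map modes from split (all-irreversible) space back to signed fluxes.

    Original reaction value = forward - reverse.  An elementary mode never
    uses both directions of one reversible reaction (only the two-cycle
    does, and those are filtered first); by default a mode violating this
    indicates an enumerator bug and raises.  ``two_cycles="net"`` instead
    nets such modes out (a retained split-pair cycle becomes an explicit
    zero row).
    """
    if two_cycles not in ("error", "net"):
        raise ValueError("two_cycles must be 'error' or 'net'")
    out = []
    for mode in modes:
        vals = []
        for rid in record.original_ids:
            fwd, bwd = record.split_pairs[rid]
            v = mode.values[fwd]
            if bwd is not None:
                r = mode.values[bwd]
                if v and r and two_cycles == "error":
                    raise ValueError(
                        f"mode uses both directions of {rid}; "
                        "two-cycles must be filtered before merging"
                    )
                v = v - r
            vals.append(v)
        out.append(FluxMode(tuple(vals), mode.kind))
    return ModeSet(tuple(record.original_ids), tuple(out))


def drop_trivial_mode(modes: ModeSet) -> ModeSet:
    """Remove the all-zero mode (the flux polyhedron's origin vertex).

    Zero flux is geometrically a valid extreme point whenever it is
    feasible, but it is not a pathway; reported mode sets exclude it.
    """
    return ModeSet(
        modes.reaction_ids, tuple(m for m in modes if m.support)
    )


def dedupe_modes(modes: Iterable[FluxMode], reaction_ids: Sequence[str]):
    """Collapse exact duplicates, reporting per-mode emission multiplicity.

    Vertex/ray enumeration in the general-polyhedron formulation may emit
    the same mode several times; the cone formulations are duplicate-free.
    Returns ``(ModeSet, report)`` with the mean multiplicity in the report.
    """
    counts: dict[FluxMode, int] = {}
    for m in modes:
        counts[m] = counts.get(m, 0) + 1
    unique = ModeSet(tuple(reaction_ids), tuple(counts))
    total = sum(counts.values())
    report = {
        "emissions": total,
        "unique": len(counts),
        "mean_multiplicity": (total / len(counts)) if counts else 0.0,
        "multiplicity": {
            str(i): counts[m] for i, m in enumerate(unique.modes)
        },
    }
    return unique, report


# ---------------------------------------------------------------------------
# analytics


def compute_yields(modes: ModeSet, substrate_id: str, target_id: str):
    """Per-mode yield ``target flux / substrate flux``.

    Modes with zero substrate flux are excluded and counted.  Returns
    ``(yields, report)`` where yields is a list of ``(mode_index, Fraction)``.
    """
    s = modes.reaction_index(substrate_id)
    t = modes.reaction_index(target_id)
    yields = []
    excluded = 0
    for i, mode in enumerate(modes):
        if mode.values[s]:
            yields.append((i, mode.values[t] / mode.values[s]))
        else:
            excluded += 1
    report = {"substrate": substrate_id, "target": target_id,
              "excluded_zero_substrate": excluded, "n_yields": len(yields)}
    return yields, report


def yield_histogram(yields, bin_edges):
    """Histogram counts of exact yields over caller-supplied bin edges."""
    vals = np.array([float(y) for _, y in yields])
    counts, edges = np.histogram(vals, bins=np.asarray(bin_edges, dtype=float))
    return edges, counts


def support_distance_matrix(modes: ModeSet) -> np.ndarray:
    """Pairwise size of the symmetric difference of mode supports."""
    masks = [m.support_bits for m in modes]
    k = len(masks)
    D = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d = (masks[i] ^ masks[j]).bit_count()
            D[i, j] = D[j, i] = d
    return D


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
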