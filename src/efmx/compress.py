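"""Loss-free stoichiometric compression and exact mode decompression.

Four null-space-based reductions shrink a model without changing its set of
elementary flux modes: dead-end removal, kernel-blocked removal, enzyme
subset merging and conservation-relation (dependent row) removal.  Every
step is logged in a :class:`CompressionRecord` so enumerated modes of the
compressed model map back exactly to the original reaction space.

All arithmetic is exact rational -- compression must be provably lossless,
so there are no tolerances anywhere in this module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from ._linalg import nullspace, rref
from .model import MetabolicModel
from .postprocess import FluxMode, ModeSet

ZERO = Fraction(0)

STEP_KINDS = (
    "deadend_removal",
    "kernel_blocked_removal",
    "enzyme_subset_merge",
    "dependent_row_removal",
)


@dataclass(frozen=True)
class CompressionStep:
    kind: str
    payload: dict

    def __post_init__(self):
        if self.kind not in STEP_KINDS:
            raise ValueError(f"unknown step kind {self.kind!r}")


@dataclass
class CompressionRecord:
    """Ordered, invertible log of compression steps."""

    steps: list[CompressionStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    # -- JSON (rationals as "p/q" strings) -------------------------------
    def to_json(self, path) -> None:
        def enc(obj):
            if isinstance(obj, Fraction):
                return f"{obj.numerator}/{obj.denominator}"
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            json.dump(
                [{"kind": s.kind, "payload": enc(s.payload)} for s in self.steps],
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CompressionRecord":
        def dec_ratio(s):
            num, den = s.split("/")
            return Fraction(int(num), int(den))

        with open(path) as fh:
            raw = json.load(fh)
        steps = []
        for item in raw:
            payload = dict(item["payload"])
            if "merges" in payload:
                payload["merges"] = [
                    {
                        "representative": m["representative"],
                        "members": [
                            (rid, dec_ratio(c)) for rid, c in m["members"]
                        ],
                    }
                    for m in payload["merges"]
                ]
            steps.append(CompressionStep(item["kind"], payload))
        return cls(steps)


# ---------------------------------------------------------------------------
# shared primitive


def rational_kernel(S: Sequence[Sequence], n: int | None = None):
    """Exact basis of ``{v : S v = 0}`` as a tuple of length-n vectors.

    The returned vectors are the columns of the kernel matrix K used by the
    null-space double description method and by the enzyme-subset test.
    """
    rows = list(S)
    if n is None:
        if not rows:
            raise ValueError("cannot infer column count from an empty matrix")
        n = len(rows[0])
    return tuple(nullspace(rows, n))


def _kernel_rows(model: MetabolicModel):
    """Per-reaction rows of the kernel matrix (reaction j -> K[j, :])."""
    K = rational_kernel(model.S, model.n_reactions)
    return [tuple(vec[j] for vec in K) for j in range(model.n_reactions)]


def _submodel(model: MetabolicModel, keep_mets, keep_rxns) -> MetabolicModel:
    return MetabolicModel(
        metabolite_ids=tuple(model.metabolite_ids[i] for i in keep_mets),
        reaction_ids=tuple(model.reaction_ids[j] for j in keep_rxns),
        S=tuple(
            tuple(model.S[i][j] for j in keep_rxns) for i in keep_mets
        ),
        rev=tuple(model.rev[j] for j in keep_rxns),
    )


# ---------------------------------------------------------------------------
# the four reductions


def remove_deadend_metabolites(model: MetabolicModel, protected=frozenset()):
    """Iteratively remove metabolites lacking a producer or a consumer,
    together with their incident reactions (which are forced to zero flux
    at steady state).  Runs to a fixpoint, so cascades are handled."""
    keep_mets = list(range(model.n_metabolites))
    keep_rxns = list(range(model.n_reactions))
    removed_mets: list[str] = []
    removed_rxns: list[str] = []
    changed = True
    while changed:
        changed = False
        for i in list(keep_mets):
            producers = consumers = 0
            for j in keep_rxns:
                x = model.S[i][j]
                if not x:
                    continue
                if model.rev[j]:
                    producers += 1
                    consumers += 1
                elif x > 0:
                    producers += 1
                else:
                    consumers += 1
            if producers == 0 or consumers == 0:
                incident = [j for j in keep_rxns if model.S[i][j]]
                if any(model.reaction_ids[j] in protected for j in incident):
                    continue
                for j in incident:
                    keep_rxns.remove(j)
                    removed_rxns.append(model.reaction_ids[j])
                keep_mets.remove(i)
                removed_mets.append(model.metabolite_ids[i])
                changed = True
    step = CompressionStep(
        "deadend_removal",
        {
            "reaction_ids_before": list(model.reaction_ids),
            "removed_reactions": removed_rxns,
            "removed_metabolites": removed_mets,
        },
    )
    return _submodel(model, keep_mets, keep_rxns), step


def remove_blocked_by_kernel(model: MetabolicModel, protected=frozenset()):
    """Remove reactions whose kernel row is identically zero: no steady
    state can carry flux through them."""
    if model.n_reactions == 0:
        return model, CompressionStep(
            "kernel_blocked_removal",
            {"reaction_ids_before": [], "removed_reactions": []},
        )
    rows = _kernel_rows(model)
    removed = [
        model.reaction_ids[j]
        for j in range(model.n_reactions)
        if not any(rows[j]) and model.reaction_ids[j] not in protected
    ]
    keep_rxns = [
        j for j in range(model.n_reactions)
        if model.reaction_ids[j] not in removed
    ]
    if not keep_rxns:
        warnings.warn("model compressed to emptiness (trivial kernel)")
    step = CompressionStep(
        "kernel_blocked_removal",
        {
            "reaction_ids_before": list(model.reaction_ids),
            "removed_reactions": removed,
        },
    )
    return _submodel(model, range(model.n_metabolites), keep_rxns), step


def merge_enzyme_subsets(model: MetabolicModel, protected=frozenset()):
    """Merge reactions whose fluxes are proportional in every steady state.

    Reactions with pairwise proportional kernel rows form an enzyme subset
    with fixed ratios ``v_j = c_j * v_merged``.  Irreversible members
    constrain the sign of the merged flux; conflicting signs block the
    whole subset.  The merged column is ``sum_j c_j S_j`` under the
    representative's id, and the ratio vector is stored for decompression.
    """
    n = model.n_reactions
    if n == 0:
        return model, CompressionStep(
            "enzyme_subset_merge",
            {"reaction_ids_before": [], "merges": [], "removed_reactions": []},
        )
    rows = _kernel_rows(model)

    groups: dict[tuple, list[int]] = {}
    for j in range(n):
        row = rows[j]
        pivot = next((x for x in row if x), None)
        if pivot is None or model.reaction_ids[j] in protected:
            groups[("solo", j)] = [j]
            continue
        key = tuple(x / pivot for x in row)
        groups.setdefault(("grp", key), []).append(j)

    merges = []
    removed: list[str] = []
    new_cols: list[tuple] = []
    new_ids: list[str] = []
    new_rev: list[bool] = []
    handled: set[int] = set()
    for j in range(n):
        if j in handled:
            continue
        group = next(g for g in groups.values() if j in g)
        handled.update(group)
        if len(group) == 1:
            new_ids.append(model.reaction_ids[j])
            new_cols.append(model.column(j))
            new_rev.append(model.rev[j])
            continue
        rep = group[0]
        prow = rows[rep]
        pidx = next(k for k, x in enumerate(prow) if x)
        coeffs = {g: rows[g][pidx] / prow[pidx] for g in group}
        # sign constraints from irreversible members
        need_pos = any(not model.rev[g] and coeffs[g] > 0 for g in group)
        need_neg = any(not model.rev[g] and coeffs[g] < 0 for g in group)
        if need_pos and need_neg:
            removed.extend(model.reaction_ids[g] for g in group)
            continue
        orient = -1 if need_neg else 1
        coeffs = {g: orient * c for g, c in coeffs.items()}
        col = tuple(
            sum(coeffs[g] * model.S[i][g] for g in group)
            for i in range(model.n_metabolites)
        )
        new_ids.append(model.reaction_ids[rep])
        new_cols.append(col)
        new_rev.append(not (need_pos or need_neg))
        merges.append(
            {
                "representative": model.reaction_ids[rep],
                "members": [(model.reaction_ids[g], coeffs[g]) for g in group],
            }
        )
    step = CompressionStep(
        "enzyme_subset_merge",
        {
            "reaction_ids_before": list(model.reaction_ids),
            "merges": merges,
            "removed_reactions": removed,
        },
    )
    out = MetabolicModel(
        metabolite_ids=model.metabolite_ids,
        reaction_ids=tuple(new_ids),
        S=tuple(
            tuple(new_cols[j][i] for j in range(len(new_cols)))
            for i in range(model.n_metabolites)
        ),
        rev=tuple(new_rev),
    )
    return out, step


def remove_dependent_rows(model: MetabolicModel):
    """Remove metabolite rows linearly dependent on preceding rows
    (conservation relations).  The kernel of S -- hence the EFM set -- is
    unchanged."""
    kept_rows: list[list[Fraction]] = []
    keep_mets: list[int] = []
    removed: list[str] = []
    current_rank = 0
    for i in range(model.n_metabolites):
        cand = kept_rows + [list(model.S[i])]
        _, pivots = rref(cand, model.n_reactions)
        if len(pivots) > current_rank:
            current_rank = len(pivots)
            kept_rows.append(list(model.S[i]))
            keep_mets.append(i)
        else:
            removed.append(model.metabolite_ids[i])
    step = CompressionStep(
        "dependent_row_removal",
        {
            "reaction_ids_before": list(model.reaction_ids),
            "removed_metabolites": removed,
        },
    )
    return _submodel(model, keep_mets, range(model.n_reactions)), step


def _step_changed(step: CompressionStep) -> bool:
    p = step.payload
    return bool(
        p.get("removed_reactions")
        or p.get("removed_metabolites")
        or p.get("merges")
    )


def compress(model: MetabolicModel, protected=frozenset()):
    """Run the four reductions to a fixpoint.

    Order per pass: dead-end removal, kernel-blocked removal, enzyme-subset
    merge, dependent-row removal; passes repeat until one full pass changes
    nothing.  Steps that change nothing are not recorded, which makes
    compression idempotent.  Reactions in *protected* (e.g. carrying user
    bounds) are never removed or merged.

    Returns ``(compressed_model, CompressionRecord)``.
    """
    record = CompressionRecord()
    current = model
    protected = frozenset(protected)
    while True:
        changed = False
        for op in (
            remove_deadend_metabolites,
            remove_blocked_by_kernel,
            merge_enzyme_subsets,
        ):
            current2, step = op(current, protected)
            if _step_changed(step):
                record.steps.append(step)
                current = current2
                changed = True
        current2, step = remove_dependent_rows(current)
        if _step_changed(step):
            record.steps.append(step)
            current = current2
            changed = True
        if not changed:
            break
    if current.n_reactions == 0 and model.n_reactions > 0:
        warnings.warn("model compressed to emptiness")
    return current, record


def decompress_modes(modes: ModeSet, record: CompressionRecord) -> ModeSet:
    """Map modes of the compressed model back to the original reactions.

    Steps are inverted in reverse order: merged fluxes distribute to
    members as ``c_j * v``; reactions removed as blocked or dead-end
    reappear with value 0.  Mode kind is preserved.
    """
    current_ids = list(modes.reaction_ids)
    vectors = [list(m.values) for m in modes]
    kinds = [m.kind for m in modes]
    for step in reversed(record.steps):
        before = step.payload["reaction_ids_before"]
        if step.kind == "dependent_row_removal":
            continue
        if step.kind in ("deadend_removal", "kernel_blocked_removal"):
            removed = set(step.payload["removed_reactions"])
            idx = {rid: k for k, rid in enumerate(current_ids)}
            missing = [
                rid for rid in current_ids
                if rid not in set(before)
            ]
            if missing:
                raise KeyError(f"modes reference unknown ids {missing}")
            new_vectors = []
            for vec in vectors:
                new_vectors.append(
                    [
                        ZERO if rid in removed else vec[idx[rid]]
                        for rid in before
                    ]
                )
            vectors = new_vectors
            current_ids = list(before)
        elif step.kind == "enzyme_subset_merge":
            removed = set(step.payload["removed_reactions"])
            member_of = {}
            for m in step.payload["merges"]:
                for rid, c in m["members"]:
                    member_of[rid] = (m["representative"], Fraction(c))
            idx = {rid: k for k, rid in enumerate(current_ids)}
            new_vectors = []
            for vec in vectors:
                row = []
                for rid in before:
                    if rid in removed:
                        row.append(ZERO)
                    elif rid in member_of:
                        rep, c = member_of[rid]
                        row.append(c * vec[idx[rep]])
                    else:
                        row.append(vec[idx[rid]])
                new_vectors.append(row)
            vectors = new_vectors
            current_ids = list(before)
    return ModeSet(
        tuple(current_ids),
        tuple(FluxMode(tuple(v), k) for v, k in zip(vectors, kinds)),
    )
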