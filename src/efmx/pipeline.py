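"""End-to-end enumeration workflows.

These helpers wire the three stages -- pre-processing (compression,
reversible splitting, geometric formulation), enumeration (double
description or reverse search), and post-processing (two-cycle filtering,
split merging, decompression) -- into single calls used by the CLI, the
tests and scripted analyses.
"""

from __future__ import annotations

from .compress import CompressionRecord, compress as _compress_model
from .compress import decompress_modes as _decompress_modes
from .ddm import enumerate_efms_ddm
from .geometry import (
    FluxCone,
    TransformRecord,
    build_polyhedron,
    dehomogenize,
    homogenize,
    split_reversible,
    to_flux_cone,
)
from .model import BoundsTable, MetabolicModel
from .postprocess import (
    ModeSet,
    dedupe_modes,
    drop_trivial_mode,
    filter_two_cycles,
    merge_split_pairs,
)
from .reverse_search import enumerate_vertices_rs

ENGINES = ("ddm", "rs")
FORMULATIONS = ("flux_cone", "polyhedral_cone", "polyhedron")


def _enumerate_cone(cone: FluxCone, engine: str, max_rays=None) -> ModeSet:
    if engine == "ddm":
        return enumerate_efms_ddm(cone, max_rays=max_rays)
    if engine == "rs":
        return enumerate_vertices_rs(cone, max_bases=max_rays).rays
    raise ValueError(f"unknown engine {engine!r}")


def enumerate_efms(
    model: MetabolicModel,
    engine: str = "ddm",
    compress: bool = True,
    max_rays: int | None = None,
) -> ModeSet:
    """All EFMs of *model* as signed flux vectors over its own reactions.

    Runs compression (optional), reversible splitting, flux-cone
    enumeration with the chosen engine, two-cycle removal, split merging
    and decompression.  Output is canonical and duplicate-free.
    """
    if compress:
        cmodel, crecord = _compress_model(model)
    else:
        cmodel, crecord = model, CompressionRecord()
    if cmodel.n_reactions == 0:
        return ModeSet(model.reaction_ids, ())
    split, trecord = split_reversible(cmodel)
    cone = FluxCone(split.S, split.reaction_ids, name="fc")
    raw = _enumerate_cone(cone, engine, max_rays)
    modes = filter_two_cycles(raw, trecord)
    modes = merge_split_pairs(modes, trecord)
    return _decompress_modes(modes, crecord)


def enumerate_efvs(
    model: MetabolicModel,
    bounds: BoundsTable,
    formulation: str = "flux_cone",
    engine: str = "ddm",
    max_rays: int | None = None,
):
    """EFVs and EFMs of the bounded flux polyhedron of *model*.

    The three formulations are mathematically equivalent; they differ in
    how the enumeration problem is posed (general polyhedron, homogenized
    polyhedral cone, or slack-embedded flux cone).  The polyhedron
    formulation may emit duplicates, which are removed here and reported.

    Returns ``(ModeSet, report)`` over the model's own (signed) reactions.
    """
    split, trecord = split_reversible(model)
    P = build_polyhedron(split, bounds, trecord)
    l = P.n_vars

    if formulation == "polyhedron":
        from .postprocess import FluxMode

        res = enumerate_vertices_rs(P, max_bases=max_rays)
        raw = [FluxMode(v, "efv") for v in res.vertex_emissions]
        raw += [FluxMode(r, "efm") for r in res.ray_emissions]
        modes, report = dedupe_modes(raw, P.var_ids)
    elif formulation == "polyhedral_cone":
        cone = homogenize(P)
        res = enumerate_vertices_rs(cone, max_bases=max_rays)
        hrecord = TransformRecord(
            P.var_ids,
            {rid: (j, None) for j, rid in enumerate(P.var_ids)},
            zeta_column=l,
        )
        modes = dehomogenize(res.rays, hrecord)
        report = {"emissions": len(modes), "mean_multiplicity": 1.0}
    elif formulation == "flux_cone":
        cone, frecord = to_flux_cone(P)
        raw = _enumerate_cone(cone, engine, max_rays)
        modes = dehomogenize(raw, frecord)
        report = {"emissions": len(modes), "mean_multiplicity": 1.0}
    else:
        raise ValueError(f"unknown formulation {formulation!r}")

    modes = filter_two_cycles(modes, trecord)
    modes = merge_split_pairs(modes, trecord)
    return drop_trivial_mode(modes), report
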