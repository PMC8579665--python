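"""Model input/output and consistency preprocessing.

SBML is read and written through lxml so that stoichiometric coefficients
and bound values travel as *decimal strings* and are converted digit-exactly
to rationals -- enumeration correctness depends on exact arithmetic, and a
float round-trip would silently corrupt coefficients such as 0.1.

Bounds of magnitude >= :data:`BIG_BOUND` (the usual COBRA "default" of
1000) are treated as unbounded: they encode "no constraint", not a capacity
constraint a modeller chose.
"""

from __future__ import annotations

import json
import os
from fractions import Fraction

from lxml import etree

from .model import BoundsTable, MetabolicModel

#: magnitude at/above which an SBML flux bound is read as "unbounded"
BIG_BOUND = Fraction(1000)
#: box constant for the consistency-check LPs
LP_BOX = 1000.0
#: tolerance below which an LP optimum counts as zero flux
LP_TOL = 1e-9

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"


class SBMLFormatError(ValueError):
    """Raised for structurally invalid SBML input."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_value(text: str, context: str) -> Fraction:
    try:
        return Fraction(text)
    except (ValueError, ZeroDivisionError):
        try:
            f = float(text)
        except ValueError:
            raise SBMLFormatError(f"non-numeric value {text!r} in {context}") from None
        if f != f or f in (float("inf"), float("-inf")):
            raise SBMLFormatError(f"non-finite value {text!r} in {context}") from None
        raise SBMLFormatError(f"unparsable numeric {text!r} in {context}") from None


def read_sbml(path) -> MetabolicModel:
    """Read an SBML L2/L3(+FBC) model into a :class:`MetabolicModel`.

    Boundary-condition species are excluded from the stoichiometric rows.
    Reversibility is taken from FBC lower bounds (``lb < 0``) when present,
    otherwise from the SBML ``reversible`` flag.
    """
    try:
        tree = etree.parse(os.fspath(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLFormatError(f"unreadable SBML file {path}: {exc}") from exc
    root = tree.getroot()
    model_el = next((c for c in root if _local(c.tag) == "model"), None)
    if model_el is None:
        raise SBMLFormatError("SBML document has no <model> element")

    params: dict[str, Fraction | None] = {}
    species_boundary: dict[str, bool] = {}
    species_order: list[str] = []
    reactions = []

    for section in model_el:
        name = _local(section.tag)
        if name == "listOfParameters":
            for p in section:
                if _local(p.tag) != "parameter":
                    continue
                pid = p.get("id")
                val = p.get("value")
                if val is None or val.upper() in ("INF", "-INF", "NAN"):
                    params[pid] = None
                else:
                    params[pid] = _parse_value(val, f"parameter {pid}")
        elif name == "listOfSpecies":
            for sp in section:
                if _local(sp.tag) != "species":
                    continue
                sid = sp.get("id")
                if sid is None:
                    raise SBMLFormatError("species without id")
                species_boundary[sid] = sp.get("boundaryCondition") == "true"
                species_order.append(sid)
        elif name == "listOfReactions":
            for rx in section:
                if _local(rx.tag) != "reaction":
                    continue
                rid = rx.get("id")
                if rid is None:
                    raise SBMLFormatError("reaction without id")
                stoich: dict[str, Fraction] = {}
                for part in rx:
                    pname = _local(part.tag)
                    sign = {"listOfReactants": -1, "listOfProducts": 1}.get(pname)
                    if sign is None:
                        continue
                    for ref in part:
                        if _local(ref.tag) != "speciesReference":
                            continue
                        sid = ref.get("species")
                        if sid is None:
                            raise SBMLFormatError(
                                f"speciesReference without species in reaction {rid}"
                            )
                        raw = ref.get("stoichiometry", "1")
                        coef = _parse_value(raw, f"reaction {rid}")
                        stoich[sid] = stoich.get(sid, Fraction(0)) + sign * coef
                lb_ref = rx.get(f"{{{FBC_NS}}}lowerFluxBound")
                ub_ref = rx.get(f"{{{FBC_NS}}}upperFluxBound")
                reactions.append(
                    (rid, rx.get("reversible") == "true", stoich, lb_ref, ub_ref)
                )

    internal = [s for s in species_order if not species_boundary[s]]
    met_index = {s: i for i, s in enumerate(internal)}
    rids, rev, lbs, ubs = [], [], [], []
    S_cols = []
    for rid, sbml_rev, stoich, lb_ref, ub_ref in reactions:
        col = [Fraction(0)] * len(internal)
        for sid, coef in stoich.items():
            if sid in met_index:
                col[met_index[sid]] = coef
        lb = params.get(lb_ref) if lb_ref is not None else None
        ub = params.get(ub_ref) if ub_ref is not None else None
        if lb_ref is not None:
            is_rev = lb is None or lb < 0
        else:
            is_rev = sbml_rev
        if lb is not None and abs(lb) >= BIG_BOUND:
            lb = None
        if ub is not None and abs(ub) >= BIG_BOUND:
            ub = None
        if not is_rev and lb is not None and lb <= 0:
            lb = None  # adds nothing beyond irreversibility
        rids.append(rid)
        rev.append(is_rev)
        lbs.append(lb)
        ubs.append(ub)
        S_cols.append(col)

    S = tuple(
        tuple(S_cols[j][i] for j in range(len(rids))) for i in range(len(internal))
    )
    return MetabolicModel(
        metabolite_ids=tuple(internal),
        reaction_ids=tuple(rids),
        S=S,
        rev=tuple(rev),
        lb=tuple(lbs),
        ub=tuple(ubs),
    )


def _decimal_string(x: Fraction) -> str:
    """Exact decimal rendering; only terminating decimals are representable."""
    num, den = x.numerator, x.denominator
    if den == 1:
        return str(num)
    d = den
    e2 = e5 = 0
    while d % 2 == 0:
        d //= 2
        e2 += 1
    while d % 5 == 0:
        d //= 5
        e5 += 1
    if d != 1:
        raise ValueError(
            f"{x} has no finite decimal representation (SBML stores decimals)"
        )
    shift = max(e2, e5)
    scaled = num * 10**shift // den
    s = str(abs(scaled)).rjust(shift + 1, "0")
    sign = "-" if scaled < 0 else ""
    return f"{sign}{s[:-shift]}.{s[-shift:]}" if shift else f"{sign}{s}"


def write_sbml(model: MetabolicModel, path) -> None:
    """Write *model* as SBML L3v1 with FBC v2 flux bounds.

    Coefficients must have terminating decimal expansions (the SBML
    ``double`` attribute cannot carry arbitrary rationals).
    """
    nsmap = {None: SBML_NS, "fbc": FBC_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap, level="3", version="1")
    root.set(f"{{{FBC_NS}}}required", "false")
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model", id="model")
    mdl.set(f"{{{FBC_NS}}}strict", "true")

    comp_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(
        comp_list, f"{{{SBML_NS}}}compartment", id="c", constant="true", size="1"
    )
    sp_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for mid in model.metabolite_ids:
        etree.SubElement(
            sp_list,
            f"{{{SBML_NS}}}species",
            id=mid,
            compartment="c",
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )
    par_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    bound_params: dict[str, str] = {}

    def bound_param(value: Fraction | None, default_inf: str) -> str:
        key = default_inf if value is None else _decimal_string(value)
        if key not in bound_params:
            pid = f"b{len(bound_params)}"
            bound_params[key] = pid
            etree.SubElement(
                par_list,
                f"{{{SBML_NS}}}parameter",
                id=pid,
                value=key,
                constant="true",
            )
        return bound_params[key]

    rx_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for j, rid in enumerate(model.reaction_ids):
        rx = etree.SubElement(
            rx_list,
            f"{{{SBML_NS}}}reaction",
            id=rid,
            reversible="true" if model.rev[j] else "false",
            fast="false",
        )
        lb = model.lb[j]
        if lb is None:
            lb_key = "-INF" if model.rev[j] else "0"
            lb_pid = bound_param(None if model.rev[j] else Fraction(0), lb_key)
        else:
            lb_pid = bound_param(lb, "")
        ub_pid = bound_param(model.ub[j], "INF")
        rx.set(f"{{{FBC_NS}}}lowerFluxBound", lb_pid)
        rx.set(f"{{{FBC_NS}}}upperFluxBound", ub_pid)
        reactants = [
            (model.metabolite_ids[i], -model.S[i][j])
            for i in range(model.n_metabolites)
            if model.S[i][j] < 0
        ]
        products = [
            (model.metabolite_ids[i], model.S[i][j])
            for i in range(model.n_metabolites)
            if model.S[i][j] > 0
        ]
        for tag, pairs in (
            ("listOfReactants", reactants),
            ("listOfProducts", products),
        ):
            if not pairs:
                continue
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}{tag}")
            for sid, coef in pairs:
                etree.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    species=sid,
                    stoichiometry=_decimal_string(coef),
                    constant="true",
                )
    etree.ElementTree(root).write(
        os.fspath(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_efmtool_inputs(model: MetabolicModel, directory, stem: str = "model"):
    """Write the efmtool-style input quadruple.

    Produces ``<stem>.sfile`` (stoichiometric matrix, whitespace-separated
    rational rows), ``<stem>.rvfile`` (0/1 reversibility line),
    ``<stem>.rfile`` (quoted reaction names) and ``<stem>.mfile`` (quoted
    metabolite names); column order equals the model's reaction order.
    """
    model.validate()
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {ext: os.path.join(directory, f"{stem}.{ext}") for ext in
             ("sfile", "rvfile", "rfile", "mfile")}
    with open(paths["sfile"], "w") as fh:
        for row in model.S:
            fh.write(" ".join(str(x) for x in row) + "\n")
    with open(paths["rvfile"], "w") as fh:
        fh.write(" ".join("1" if r else "0" for r in model.rev) + "\n")
    with open(paths["rfile"], "w") as fh:
        fh.write(" ".join(f'"{r}"' for r in model.reaction_ids) + "\n")
    with open(paths["mfile"], "w") as fh:
        fh.write(" ".join(f'"{m}"' for m in model.metabolite_ids) + "\n")
    return paths["sfile"], paths["rvfile"], paths["rfile"], paths["mfile"]


def apply_bounds(model: MetabolicModel, bounds: BoundsTable) -> MetabolicModel:
    """Tighten the model's flux bounds by the entries of *bounds*.

    Bounds only ever shrink the feasible box (idempotent, monotone); the
    input model is unmodified.
    """
    lb = list(model.lb)
    ub = list(model.ub)
    for rid, rel, val in bounds.entries:
        j = model.reaction_index(rid)
        if rel == ">=":
            cur = lb[j]
            if cur is None and not model.rev[j]:
                cur = Fraction(0)
            lb[j] = val if cur is None else max(cur, val)
        else:
            ub[j] = val if ub[j] is None else min(ub[j], val)
        if lb[j] is not None and ub[j] is not None and lb[j] > ub[j]:
            raise ValueError(f"bounds make lb > ub for reaction {rid}")
    return model.with_(lb=tuple(lb), ub=tuple(ub))


def make_consistent(model: MetabolicModel):
    """Remove blocked reactions, fix one-directional reversibles, drop orphans.

    For each reaction the flux range over ``{S v = 0, box bounds}`` is
    computed by a pair of LPs (box: ``[0, M]`` irreversible, ``[-M, M]``
    reversible).  Reactions whose range collapses to zero are removed;
    reversible reactions that can only run one way are made irreversible
    (flipping the column sign when only the reverse direction works).
    Metabolites left without any incident reaction are removed.

    Returns ``(consistent_model, report)`` where the report lists every
    change.  The LP step is the single floating-point stage of the
    pipeline; all structural edits remain exact.
    """
    import numpy as np
    from scipy.optimize import linprog

    m, n = model.n_metabolites, model.n_reactions
    report = {
        "removed_reactions": [],
        "made_irreversible_forward": [],
        "made_irreversible_flipped": [],
        "removed_metabolites": [],
    }
    if n == 0:
        return model, report
    A_eq = np.array([[float(x) for x in row] for row in model.S]) if m else None
    box = [(-LP_BOX, LP_BOX) if r else (0.0, LP_BOX) for r in model.rev]
    vmin = []
    vmax = []
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo = linprog(c, A_eq=A_eq, b_eq=np.zeros(m) if m else None,
                     bounds=box, method="highs")
        c[j] = -1.0
        hi = linprog(c, A_eq=A_eq, b_eq=np.zeros(m) if m else None,
                     bounds=box, method="highs")
        if not (lo.success and hi.success):
            raise RuntimeError(
                f"LP failed for reaction {model.reaction_ids[j]}"
            )
        vmin.append(lo.fun)
        vmax.append(-hi.fun)

    keep: list[int] = []
    flip: set[int] = set()
    new_rev = []
    for j in range(n):
        rid = model.reaction_ids[j]
        blocked = abs(vmin[j]) <= LP_TOL and abs(vmax[j]) <= LP_TOL
        if blocked:
            report["removed_reactions"].append(rid)
            continue
        keep.append(j)
        if model.rev[j] and vmin[j] >= -LP_TOL:
            new_rev.append(False)
            report["made_irreversible_forward"].append(rid)
        elif model.rev[j] and vmax[j] <= LP_TOL:
            new_rev.append(False)
            flip.add(j)
            report["made_irreversible_flipped"].append(rid)
        else:
            new_rev.append(model.rev[j])

    cols = {}
    for j in keep:
        col = [model.S[i][j] for i in range(m)]
        if j in flip:
            col = [-x for x in col]
        cols[j] = col
    keep_mets = [
        i for i in range(m) if any(cols[j][i] for j in keep)
    ]
    report["removed_metabolites"] = [
        model.metabolite_ids[i] for i in range(m) if i not in set(keep_mets)
    ]
    new_model = MetabolicModel(
        metabolite_ids=tuple(model.metabolite_ids[i] for i in keep_mets),
        reaction_ids=tuple(model.reaction_ids[j] for j in keep),
        S=tuple(tuple(cols[j][i] for j in keep) for i in keep_mets),
        rev=tuple(new_rev),
        lb=tuple(
            Fraction(0) if (j in flip or not nr) and (model.lb[j] is None or model.lb[j] < 0)
            else (model.lb[j] if j not in flip else None)
            for j, nr in zip(keep, new_rev)
        ),
        ub=tuple(None if j in flip else model.ub[j] for j in keep),
        objective_id=model.objective_id
        if model.objective_id in {model.reaction_ids[j] for j in keep}
        else None,
    )
    return new_model, report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
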