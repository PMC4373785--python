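"""Metabolic model representation and SBML import/export.

A :class:`MetabolicModel` is an ordered collection of reactions over a set of
metabolites.  Metabolites flagged as *boundary* (external) are not balanced
to zero in the steady-state analysis; everything else is internal and
contributes a row to the stoichiometric matrix.  Reaction order is stable and
defines the component order of every flux vector derived from the model.

Gene-reaction associations are boolean expressions over gene identifiers
(AND for enzyme complexes, OR for isoenzymes) in the BiGG/COBRA
``GENE_ASSOCIATION`` note syntax.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import libsbml
import numpy as np
import pandas as pd

from .errors import FormatError, ModelIntegrityError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "read_sbml",
    "write_sbml",
    "select_submodel",
    "remove_reactions",
    "extract_gene_associations",
    "stoichiometric_matrix",
    "export_stoichiometric_matrix",
    "parse_gene_association",
    "gene_association_genes",
]


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``is_boundary`` marks external metabolites that are exchanged with the
    environment and therefore not balanced to zero at steady state.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    is_boundary: bool = False

    def __post_init__(self):
        if not self.compartment:
            raise ModelIntegrityError(f"metabolite {self.id!r}: empty compartment")


@dataclass
class Reaction:
    """A (possibly reversible) biochemical reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    coefficients are consumed (substrates), positive produced (products).
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = True
    gene_association: str | None = None

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelIntegrityError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    """An ordered reaction network with pathway annotations."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    annotations: dict[str, list[str]] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index()[mid]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def validate(self) -> None:
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelIntegrityError(f"duplicate metabolite ids: {dupes}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelIntegrityError(f"duplicate reaction ids: {dupes}")
        known = set(mids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            annotations={k: list(v) for k, v in self.annotations.items()},
            id=self.id,
        )


# ---------------------------------------------------------------------------
# Gene association parsing
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize_gpr(expr: str) -> list[str]:
    return _GPR_TOKEN.findall(expr)


def parse_gene_association(expr: str):
    """Parse a boolean gene association into an AST.

    Returns nested tuples: ``("gene", id)``, ``("and", [children])`` or
    ``("or", [children])``.  ``and``/``or`` are case-insensitive; parentheses
    group as usual.
    """
    tokens = _tokenize_gpr(expr)
    if not tokens:
        raise FormatError(f"empty gene association: {expr!r}")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_factor():
        tok = peek()
        if tok is None:
            raise FormatError(f"unexpected end of gene association: {expr!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise FormatError(f"unbalanced parentheses in: {expr!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"unexpected token {tok!r} in: {expr!r}")
        return ("gene", advance())

    ast = parse_or()
    if pos != len(tokens):
        raise FormatError(f"trailing tokens in gene association: {expr!r}")
    return ast


def gene_association_genes(expr: str) -> list[str]:
    """Flatten a boolean association to the ordered set of mentioned genes."""
    ast = parse_gene_association(expr)
    genes: list[str] = []

    def walk(node):
        if node[0] == "gene":
            if node[1] not in genes:
                genes.append(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(ast)
    return genes


def extract_gene_associations(model: MetabolicModel) -> dict[str, list[str]]:
    """Map each reaction with an association to its flattened gene list.

    Reactions without an association are absent from the map.  The original
    boolean expression stays available on each :class:`Reaction` for
    policy-aware aggregation.
    """
    out: dict[str, list[str]] = {}
    for r in model.reactions:
        if r.gene_association:
            try:
                out[r.id] = gene_association_genes(r.gene_association)
            except FormatError as exc:
                raise FormatError(
                    f"malformed gene association on reaction {r.id!r}: {exc}"
                ) from exc
    return out


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel):
    """Build the stoichiometric matrix E over internal metabolites.

    Rows are internal (non-boundary) metabolites, columns are reactions in
    model order; entry (i, j) is the signed coefficient of metabolite i in
    reaction j.  Boundary metabolites are excluded because they are not
    balanced to zero.

    Returns ``(E, row_labels, column_labels)``.
    """
    internal = [m.id for m in model.metabolites if not m.is_boundary]
    ridx = {m: i for i, m in enumerate(internal)}
    cols = model.reaction_ids
    E = np.zeros((len(internal), len(cols)))
    for j, r in enumerate(model.reactions):
        for m, c in r.stoichiometry.items():
            i = ridx.get(m)
            if i is not None:
                E[i, j] += c
    return E, internal, cols


def export_stoichiometric_matrix(model: MetabolicModel, path) -> None:
    """Write E as CSV: header row = reaction ids, first column = metabolite ids."""
    E, rows, cols = stoichiometric_matrix(model)
    pd.DataFrame(E, index=rows, columns=cols).to_csv(path)


# ---------------------------------------------------------------------------
# Sub-network assembly
# ---------------------------------------------------------------------------

def select_submodel(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    pathways: list[str] | None = None,
    genes: list[str] | None = None,
) -> MetabolicModel:
    """Select the union of reactions matching any of the given selectors.

    ``pathways`` match the model's pathway annotations; ``genes`` match
    reactions whose gene association mentions the gene.  The returned model
    keeps only the metabolites referenced by the selected reactions.  A
    selector matching nothing yields an empty model with a warning.
    """
    if reaction_ids is None and pathways is None and genes is None:
        raise ValueError("provide at least one selector")
    selected: set[str] = set()
    if reaction_ids:
        selected.update(reaction_ids)
    if pathways:
        for p in pathways:
            selected.update(model.annotations.get(p, []))
    if genes:
        assoc = extract_gene_associations(model)
        for g in genes:
            selected.update(rid for rid, gs in assoc.items() if g in gs)
    rxns = [r for r in model.reactions if r.id in selected]
    if not rxns:
        warnings.warn("submodel selection matched no reactions", stacklevel=2)
    used = {m for r in rxns for m in r.stoichiometry}
    mets = [m for m in model.metabolites if m.id in used]
    rids = {r.id for r in rxns}
    annotations = {
        p: [rid for rid in lst if rid in rids]
        for p, lst in model.annotations.items()
        if any(rid in rids for rid in lst)
    }
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          annotations=annotations, id=model.id)


def remove_reactions(model: MetabolicModel, reaction_ids: list[str]) -> MetabolicModel:
    """Return a model without the listed reactions; orphaned metabolites are dropped."""
    known = set(model.reaction_ids)
    unknown = [rid for rid in reaction_ids if rid not in known]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    drop = set(reaction_ids)
    rxns = [r for r in model.reactions if r.id not in drop]
    used = {m for r in rxns for m in r.stoichiometry}
    mets = [m for m in model.metabolites if m.id in used]
    rids = {r.id for r in rxns}
    annotations = {
        p: [rid for rid in lst if rid in rids]
        for p, lst in model.annotations.items()
        if any(rid in rids for rid in lst)
    }
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          annotations=annotations, id=model.id)


# ---------------------------------------------------------------------------
# SBML import/export
# ---------------------------------------------------------------------------

_GA_NOTE = re.compile(r"GENE_ASSOCIATION:\s*([^<\n]*)", re.IGNORECASE)
_SS_NOTE = re.compile(r"SUBSYSTEM:\s*([^<\n]*)", re.IGNORECASE)


def read_sbml(
    path,
    boundary_suffix: str = "_b",
    boundary_compartments: tuple[str, ...] = (),
) -> MetabolicModel:
    """Import an SBML Level 2/3 document as a :class:`MetabolicModel`.

    A species is treated as boundary (external) when its SBML
    ``boundaryCondition`` attribute is true, when its id ends in
    ``boundary_suffix`` (the BiGG ``_b`` convention), or when its compartment
    is one of ``boundary_compartments``.  Gene associations and pathway
    (subsystem) labels are parsed from COBRA-style reaction notes.
    """
    doc = libsbml.readSBML(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise FormatError(
                f"SBML parse failure at line {err.getLine()}: {err.getMessage()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"no model element in SBML document {path}")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        comp = sp.getCompartment() or "c"
        boundary = (
            bool(sp.getBoundaryCondition())
            or (boundary_suffix and sp.getId().endswith(boundary_suffix))
            or comp in boundary_compartments
        )
        metabolites.append(
            Metabolite(id=sp.getId(), name=sp.getName() or "",
                       compartment=comp, is_boundary=boundary)
        )
    declared = {m.id for m in metabolites}

    reactions = []
    annotations: dict[str, list[str]] = {}
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref, sign in ((rxn.getListOfReactants(), -1.0), (rxn.getListOfProducts(), 1.0)):
            for sr in ref:
                sid = sr.getSpecies()
                if sid not in declared:
                    raise ModelIntegrityError(
                        f"reaction {rxn.getId()!r} references undeclared species {sid!r}"
                    )
                coeff = sr.getStoichiometry()
                if np.isnan(coeff):
                    coeff = 1.0
                # duplicate references to one species are summed (net stoichiometry)
                stoich[sid] = stoich.get(sid, 0.0) + sign * coeff
        gene_association = None
        notes = rxn.getNotesString() if rxn.isSetNotes() else ""
        m = _GA_NOTE.search(notes)
        if m and m.group(1).strip():
            gene_association = m.group(1).strip()
        reversible = rxn.getReversible()
        reactions.append(
            Reaction(id=rxn.getId(), name=rxn.getName() or "",
                     stoichiometry=stoich, reversible=reversible,
                     gene_association=gene_association)
        )
        m = _SS_NOTE.search(notes)
        if m and m.group(1).strip():
            annotations.setdefault(m.group(1).strip(), []).append(rxn.getId())

    return MetabolicModel(
        metabolites=metabolites, reactions=reactions,
        annotations=annotations, id=sbml_model.getId() or "model",
    )


def write_sbml(model: MetabolicModel, path) -> None:
    """Export a model as SBML Level 3 Version 1 (no packages).

    The emitted document round-trips through :func:`read_sbml`: reaction ids,
    net stoichiometries, reversibility flags, boundary flags, gene
    associations and pathway labels are all preserved.
    """
    doc = libsbml.SBMLDocument(3, 1)
    sm = doc.createModel()
    sm.setId(model.id)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(bool(met.is_boundary))
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    pathway_of = {
        rid: p for p, lst in model.annotations.items() for rid in lst
    }
    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId(rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setReversible(bool(rxn.reversible))
        r.setFast(False)
        for mid, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                sr = r.createReactant()
                sr.setStoichiometry(-coeff)
            elif coeff > 0:
                sr = r.createProduct()
                sr.setStoichiometry(coeff)
            else:
                continue
            sr.setSpecies(mid)
            sr.setConstant(True)
        note_lines = []
        if rxn.gene_association:
            note_lines.append(f"GENE_ASSOCIATION: {rxn.gene_association}")
        if rxn.id in pathway_of:
            note_lines.append(f"SUBSYSTEM: {pathway_of[rxn.id]}")
        if note_lines:
            body = "".join(f"<p>{line}</p>" for line in note_lines)
            r.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")
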