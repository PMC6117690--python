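"""Stoichiometric model container, loaders, and the packaged toy network.

Models can be loaded from SBML (via cobrapy/libsbml) or from a simple
TSV dialect — one reaction per row::

    rxn_id<TAB>subsystem<TAB>lb<TAB>ub<TAB>equation

with equations like ``1 ga3p_c + 1 pyr_c -> 1 dxp_c``. Metabolites with
no products (or no substrates) denote exchange across the system
boundary, e.g. ``-> ga3p_c`` for uptake and ``fuco_c ->`` for export.

The packaged toy network mirrors the precursor-sharing structure of
diatom pigment metabolism: glyceraldehyde 3-phosphate (GA3P) and
pyruvate feed 1-deoxy-D-xylulose 5-phosphate (DXP) synthesis, DXP leads
to geranylgeranyl pyrophosphate (GGPP), and GGPP is split between the
fucoxanthin branch (via phytoene) and the chlorophyll-a branch (via
phytyl-PP + chlorophyllide); pyruvate also feeds acetyl-CoA and a
fatty-acid elongation chain in lipid metabolism. The committed GGPP
supply step carries fixed bounds so that branch-competition correlation
signs are analytically known.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "MetabolicModel",
    "load_model",
    "parse_tsv_model",
    "model_to_tsv",
    "build_toy_network",
    "toy_network_path",
    "TOY_TARGET_REACTION",
    "find_blocked_reactions",
]

#: Default correlation target in the toy network: the committed
#: fucoxanthin-synthesis step.
TOY_TARGET_REACTION = "FUCO_SYN"


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry map (metabolite -> coefficient,
    negative = consumed) plus flux bounds and a pathway label."""

    rxn_id: str
    stoichiometry: Mapping[str, float]
    lb: float
    ub: float
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"{self.rxn_id}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds and subsystem annotations."""

    metabolites: list[str]
    reactions: list[Reaction]
    target_reaction_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        declared = set(self.metabolites)
        for rxn in self.reactions:
            undeclared = set(rxn.stoichiometry) - declared
            if undeclared:
                raise ValueError(
                    f"reaction {rxn.rxn_id} references undeclared metabolite(s) "
                    f"{sorted(undeclared)}"
                )
        ids = [r.rxn_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        if self.target_reaction_id is not None and self.target_reaction_id not in ids:
            raise ValueError(f"target reaction {self.target_reaction_id!r} not in model")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.rxn_id for r in self.reactions]

    @property
    def subsystems(self) -> dict[str, str]:
        return {r.rxn_id: r.subsystem for r in self.reactions}

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"no reaction {rxn_id!r} in model") from None

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); steady state is S @ v = 0."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_idx[met], j] = coef
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def to_cobra(self):
        """Convert to a cobrapy Model (for SBML export / cross-checks)."""
        import cobra

        model = cobra.Model(self.name or "model")
        mets = {m: cobra.Metabolite(m, compartment=m.rsplit("_", 1)[-1]) for m in self.metabolites}
        rxns = []
        for r in self.reactions:
            cr = cobra.Reaction(r.rxn_id, lower_bound=r.lb, upper_bound=r.ub)
            cr.subsystem = r.subsystem
            rxns.append(cr)
        model.add_reactions(rxns)
        for r, cr in zip(self.reactions, rxns):
            cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        return model


# ---------------------------------------------------------------------------
# parsing

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, rxn_id: str, sign: float) -> dict[str, float]:
    stoich: dict[str, float] = {}
    side = side.strip()
    if not side:
        return stoich
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"reaction {rxn_id}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef
    return stoich


def parse_reaction_equation(equation: str, rxn_id: str = "?") -> dict[str, float]:
    """Parse ``1 a_c + 2 b_c -> 1 c_c`` into a stoichiometry map.

    ``<->`` (or ``<=>``) denotes reversibility at the equation level but
    bounds come from the TSV columns; an empty side denotes exchange with
    the environment.
    """
    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise ValueError(f"reaction {rxn_id}: no arrow in equation {equation!r}")
    stoich = _parse_side(left, rxn_id, -1.0)
    for met, coef in _parse_side(right, rxn_id, +1.0).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ValueError(f"reaction {rxn_id}: equation has empty net stoichiometry")
    return stoich


def parse_tsv_model(
    text: str, target_reaction_id: str | None = None, name: str = ""
) -> MetabolicModel:
    """Parse the TSV reaction dialect (see module docstring).

    Lines starting with ``#`` and blank lines are ignored; metabolites
    are declared implicitly by their appearance in equations.
    """
    reactions: list[Reaction] = []
    metabolites: list[str] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(
                f"line {lineno}: expected 5 tab-separated fields "
                f"(rxn_id, subsystem, lb, ub, equation), got {len(parts)}"
            )
        rxn_id, subsystem, lb_s, ub_s, equation = parts
        try:
            lb, ub = float(lb_s), float(ub_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno} ({rxn_id}): non-numeric bound") from exc
        try:
            stoich = parse_reaction_equation(equation, rxn_id)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        reactions.append(Reaction(rxn_id, stoich, lb, ub, subsystem))
        for met in stoich:
            if met not in seen:
                seen.add(met)
                metabolites.append(met)
    return MetabolicModel(metabolites, reactions, target_reaction_id, name=name)


def load_model(
    path: str | Path,
    fmt: str | None = None,
    target_reaction_id: str | None = None,
) -> MetabolicModel:
    """Load a model from SBML or the TSV dialect.

    ``fmt`` is ``"sbml"`` or ``"tsv"``; inferred from the file suffix
    when omitted (``.xml``/``.sbml`` -> SBML).
    """
    path = Path(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if fmt == "tsv":
        return parse_tsv_model(
            path.read_text(), target_reaction_id=target_reaction_id, name=path.stem
        )
    if fmt == "sbml":
        import cobra

        cm = cobra.io.read_sbml_model(str(path))
        metabolites = [m.id for m in cm.metabolites]
        reactions = [
            Reaction(
                r.id,
                {m.id: c for m, c in r.metabolites.items()},
                r.lower_bound,
                r.upper_bound,
                r.subsystem or "",
            )
            for r in cm.reactions
        ]
        return MetabolicModel(metabolites, reactions, target_reaction_id, name=cm.id or path.stem)
    raise ValueError(f"unknown model format {fmt!r}")


def _format_side(stoich: Mapping[str, float], sign: float) -> str:
    terms = [
        f"{abs(c):g} {m}"
        for m, c in stoich.items()
        if (c < 0) == (sign < 0) and c != 0
    ]
    return " + ".join(terms)


def model_to_tsv(model: MetabolicModel) -> str:
    """Serialise a model to the TSV reaction dialect (round-trips with
    :func:`parse_tsv_model` up to metabolite ordering)."""
    lines = ["# rxn_id\tsubsystem\tlb\tub\tequation"]
    for r in model.reactions:
        eq = f"{_format_side(r.stoichiometry, -1)} -> {_format_side(r.stoichiometry, +1)}"
        lines.append(f"{r.rxn_id}\t{r.subsystem}\t{r.lb:g}\t{r.ub:g}\t{eq}")
    return "\n".join(lines) + "\n"


def toy_network_path() -> Path:
    """Path of the packaged toy-network TSV (same model as
    :func:`build_toy_network`)."""
    return Path(__file__).parent / "data" / "toy_pigment_network.tsv"


# ---------------------------------------------------------------------------
# analysis helpers


def find_blocked_reactions(model: MetabolicModel, tol: float = 1e-9) -> list[str]:
    """Reactions that can carry no flux anywhere in the steady-state
    polytope (flux-variability min = max = 0)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    blocked = []
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        extremes = []
        for sign in (+1.0, -1.0):
            res = linprog(
                sign * c,
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lb, ub)),
                method="highs",
            )
            if not res.success:
                raise RuntimeError(f"FVA LP failed for {model.reaction_ids[j]}: {res.message}")
            extremes.append(res.x[j])
        if max(abs(e) for e in extremes) <= tol:
            blocked.append(model.reaction_ids[j])
    return blocked


# ---------------------------------------------------------------------------
# the packaged toy network


def build_toy_network() -> MetabolicModel:
    """The packaged ~15-reaction pigment/lipid precursor network.

    Structure (all metabolites in the chloroplast/cytosol compartment
    ``c`` unless noted):

    * uptake of GA3P and pyruvate;
    * DXP synthase combines both into DXP; a committed, fixed-rate step
      turns DXP into GGPP (lb = ub = 1 — the shared precursor pool);
    * **fucoxanthin branch**: GGPP -> phytoene (phytoene synthase) ->
      fucoxanthin -> export; ``FUCO_SYN`` is the correlation target;
    * **chlorophyll branch**: GGPP -> phytyl-PP (geranylgeranyl
      reductase); GA3P-derived chlorophyllide + phytyl-PP -> chlorophyll
      a (chlorophyll synthase) -> sink;
    * **lipid branch**: pyruvate -> acetyl-CoA (pyruvate dehydrogenase)
      -> fatty acids (elongation) -> sink;
    * a disconnected two-reaction pair (orphan metabolite import/export)
      as an independence control.

    Because the GGPP supply is fixed at 1, the fucoxanthin and
    chlorophyll branches split a constant pool: fluxes in the fucoxanthin
    branch correlate +1 with the target, the chlorophyll branch -1, the
    lipid branch and the disconnected pair ~0, and the fixed upstream
    steps have zero variance.
    """
    rxns = [
        Reaction("EX_GA3P", {"ga3p_c": +1.0}, 0.0, 10.0, "uptake"),
        Reaction("EX_PYR", {"pyr_c": +1.0}, 0.0, 10.0, "uptake"),
        Reaction("DXS", {"ga3p_c": -1.0, "pyr_c": -1.0, "dxp_c": +1.0}, 0.0, 10.0,
                 "terpenoid backbone"),
        # committed precursor supply: fixed flux defines the shared GGPP pool
        Reaction("GGPP_SYN", {"dxp_c": -1.0, "ggpp_c": +1.0}, 1.0, 1.0,
                 "terpenoid backbone"),
        # fucoxanthin branch
        Reaction("PSY", {"ggpp_c": -1.0, "phytoene_c": +1.0}, 0.0, 10.0,
                 "carotenoid biosynthesis"),
        Reaction("FUCO_SYN", {"phytoene_c": -1.0, "fuco_c": +1.0}, 0.0, 10.0,
                 "carotenoid biosynthesis"),
        Reaction("EX_FUCO", {"fuco_c": -1.0}, 0.0, 10.0, "carotenoid biosynthesis"),
        # chlorophyll branch
        Reaction("GGR", {"ggpp_c": -1.0, "phytylpp_c": +1.0}, 0.0, 10.0,
                 "porphyrin and chlorophyll metabolism"),
        Reaction("CHLIDE_SYN", {"ga3p_c": -1.0, "chlide_c": +1.0}, 0.0, 10.0,
                 "porphyrin and chlorophyll metabolism"),
        Reaction("CHLG", {"phytylpp_c": -1.0, "chlide_c": -1.0, "chla_c": +1.0}, 0.0, 10.0,
                 "porphyrin and chlorophyll metabolism"),
        Reaction("EX_CHLA", {"chla_c": -1.0}, 0.0, 10.0,
                 "porphyrin and chlorophyll metabolism"),
        # lipid branch
        Reaction("PDH", {"pyr_c": -1.0, "accoa_c": +1.0}, 0.0, 10.0, "lipid metabolism"),
        Reaction("FAS", {"accoa_c": -1.0, "fa_c": +1.0}, 0.0, 10.0,
                 "lipid metabolism"),
        Reaction("EX_FA", {"fa_c": -1.0}, 0.0, 10.0, "lipid metabolism"),
        # disconnected control pair
        Reaction("DISC_IN", {"orphan_c": +1.0}, 0.0, 5.0, "disconnected control"),
        Reaction("DISC_OUT", {"orphan_c": -1.0}, 0.0, 5.0, "disconnected control"),
    ]
    metabolites = []
    seen: set[str] = set()
    for r in rxns:
        for m in r.stoichiometry:
            if m not in seen:
                seen.add(m)
                metabolites.append(m)
    return MetabolicModel(
        metabolites, rxns, target_reaction_id=TOY_TARGET_REACTION, name="toy_pigment_network"
    )
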