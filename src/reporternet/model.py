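"""Gene–reaction–metabolite–pathway association structure.

The scoring layers of the analysis only need two association tables: which
genes (via the reactions they catalyse) touch which metabolites, and which
metabolites belong to which pathways.  A reaction layer is optional —
AraCyc-style exports carry gene→reaction→metabolite triples, while flat
gene–metabolite tables are accepted directly.  Ubiquitous currency
metabolites (ATP, NADH, water, proton, ...) are excluded from scoring
because their extreme connectivity swamps neighborhood aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .exceptions import StructuralError, ValidationError

logger = logging.getLogger(__name__)

#: Currency metabolites excluded from reporter scoring by default.
DEFAULT_CURRENCY: frozenset[str] = frozenset(
    {
        "proton",
        "water",
        "oxygen molecule",
        "NADH",
        "NAD+",
        "NADPH",
        "NADP+",
        "ATP",
        "ADP",
        "AMP",
        "GTP",
        "GDP",
        "UDP",
        "CoA",
        "FAD",
        "diphosphate",
        "carbon dioxide",
        "carbon monoxide",
        "phosphate",
        "ammonia",
        "hydrogen peroxide",
        "oxidized electron acceptor",
        "reduced electron acceptor",
    }
)


@dataclass(frozen=True)
class MetabolicModel:
    """Validated association structure with a currency exclusion set.

    ``gene_metabolite`` is always populated; when a reaction layer is
    present it equals the composition of ``gene_reaction`` and
    ``reaction_metabolite``.  All association sets keep their full content;
    currency filtering is applied by the scoring views (:meth:`neighbors`,
    :meth:`pathway_members`, :attr:`scoreable_metabolites`).
    """

    genes: frozenset[str]
    metabolites: frozenset[str]
    pathways: frozenset[str]
    gene_metabolite: frozenset[tuple[str, str]]
    metabolite_pathway: frozenset[tuple[str, str]]
    reactions: frozenset[str] = frozenset()
    gene_reaction: frozenset[tuple[str, str]] = frozenset()
    reaction_metabolite: frozenset[tuple[str, str]] = frozenset()
    currency: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for g, m in self.gene_metabolite:
            if g not in self.genes or m not in self.metabolites:
                raise StructuralError(f"gene_metabolite pair ({g!r}, {m!r}) has undeclared endpoint")
        for m, p in self.metabolite_pathway:
            if m not in self.metabolites or p not in self.pathways:
                raise StructuralError(f"metabolite_pathway pair ({m!r}, {p!r}) has undeclared endpoint")
        for g, r in self.gene_reaction:
            if g not in self.genes or r not in self.reactions:
                raise StructuralError(f"gene_reaction pair ({g!r}, {r!r}) has undeclared endpoint")
        for r, m in self.reaction_metabolite:
            if r not in self.reactions or m not in self.metabolites:
                raise StructuralError(f"reaction_metabolite pair ({r!r}, {m!r}) has undeclared endpoint")

    # ------------------------------------------------------------------ views

    @property
    def has_reaction_layer(self) -> bool:
        return bool(self.reactions)

    @property
    def scoreable_metabolites(self) -> frozenset[str]:
        return self.metabolites - self.currency

    def neighbors(self, metabolite: str) -> frozenset[str]:
        """Genes associated with a metabolite, after currency filtering."""
        if metabolite not in self.metabolites:
            raise KeyError(f"unknown metabolite {metabolite!r}")
        if metabolite in self.currency:
            return frozenset()
        return frozenset(g for g, m in self.gene_metabolite if m == metabolite)

    def reaction_neighbors(self, metabolite: str) -> frozenset[str]:
        """Reactions touching a metabolite, after currency filtering."""
        if metabolite not in self.metabolites:
            raise KeyError(f"unknown metabolite {metabolite!r}")
        if metabolite in self.currency:
            return frozenset()
        return frozenset(r for r, m in self.reaction_metabolite if m == metabolite)

    def pathway_members(self, pathway: str) -> frozenset[str]:
        """Scoreable (non-currency) member metabolites of a pathway."""
        if pathway not in self.pathways:
            raise KeyError(f"unknown pathway {pathway!r}")
        return frozenset(m for m, p in self.metabolite_pathway if p == pathway) - self.currency

    def pathway_members_all(self, pathway: str) -> frozenset[str]:
        """Full pathway membership, currency included (for reporting)."""
        if pathway not in self.pathways:
            raise KeyError(f"unknown pathway {pathway!r}")
        return frozenset(m for m, p in self.metabolite_pathway if p == pathway)

    def reactions_of_gene(self, gene: str) -> frozenset[str]:
        return frozenset(r for g, r in self.gene_reaction if g == gene)


def _read_pairs(table, n_cols_expected) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t", dtype=str)
    else:
        df = table.copy().astype(str)
    if df.shape[1] not in n_cols_expected:
        raise StructuralError(
            f"association table has {df.shape[1]} columns, expected one of {n_cols_expected}"
        )
    if df.isna().any().any() or (df == "").any().any():
        raise ValidationError("association table contains empty ids")
    return df


def load_model(
    gene_metabolite_table,
    metabolite_pathway_table,
    gene_reaction_table=None,
    *,
    genes: Optional[Iterable[str]] = None,
    metabolites: Optional[Iterable[str]] = None,
    pathways: Optional[Iterable[str]] = None,
) -> MetabolicModel:
    """Load a metabolic model from TSV paths or DataFrames.

    ``gene_metabolite_table`` may carry two columns (gene_id, metabolite_id)
    or three (gene_id, reaction_id, metabolite_id); the three-column form
    populates the reaction layer and derives gene–metabolite pairs by
    composition.  Explicitly supplied id sets turn dangling references into
    validation errors; otherwise id sets are inferred from the tables.
    Duplicate rows collapse to single pairs; orphan ids are retained and
    counted in the load report (logged).
    """
    gm = _read_pairs(gene_metabolite_table, (2, 3))
    mp = _read_pairs(metabolite_pathway_table, (2,))

    reactions: set[str] = set()
    gene_reaction: set[tuple[str, str]] = set()
    reaction_metabolite: set[tuple[str, str]] = set()

    if gm.shape[1] == 3:
        triples = {tuple(r) for r in gm.itertuples(index=False)}
        gene_reaction = {(g, rx) for g, rx, _ in triples}
        reaction_metabolite = {(rx, m) for _, rx, m in triples}
        gene_metabolite = {(g, m) for g, _, m in triples}
        reactions = {rx for _, rx in gene_reaction}
    else:
        gene_metabolite = {tuple(r) for r in gm.itertuples(index=False)}

    if gene_reaction_table is not None:
        gr = _read_pairs(gene_reaction_table, (2,))
        gene_reaction |= {tuple(r) for r in gr.itertuples(index=False)}
        reactions |= {rx for _, rx in gene_reaction}

    metabolite_pathway = {tuple(r) for r in mp.itertuples(index=False)}

    seen_genes = {g for g, _ in gene_metabolite} | {g for g, _ in gene_reaction}
    seen_mets = {m for _, m in gene_metabolite} | {m for m, _ in metabolite_pathway} | {
        m for _, m in reaction_metabolite
    }
    seen_paths = {p for _, p in metabolite_pathway}

    def resolve(declared, seen, kind):
        if declared is None:
            return frozenset(seen)
        declared = frozenset(declared)
        dangling = sorted(seen - declared)
        if dangling:
            raise StructuralError(f"dangling {kind} references: {dangling[:10]}")
        return declared

    genes_f = resolve(genes, seen_genes, "gene")
    mets_f = resolve(metabolites, seen_mets, "metabolite")
    paths_f = resolve(pathways, seen_paths, "pathway")

    n_orphan_mets = len(mets_f - {m for m, _ in metabolite_pathway})
    n_orphan_genes = len(genes_f - {g for g, _ in gene_metabolite})
    logger.info(
        "loaded model: %d genes, %d metabolites, %d pathways "
        "(%d metabolites without pathway, %d genes without metabolite)",
        len(genes_f), len(mets_f), len(paths_f), n_orphan_mets, n_orphan_genes,
    )

    return MetabolicModel(
        genes=genes_f,
        metabolites=mets_f,
        pathways=paths_f,
        gene_metabolite=frozenset(gene_metabolite),
        metabolite_pathway=frozenset(metabolite_pathway),
        reactions=frozenset(reactions),
        gene_reaction=frozenset(gene_reaction),
        reaction_metabolite=frozenset(reaction_metabolite),
    )


def remove_currency(model: MetabolicModel, currency_list: Iterable[str] = DEFAULT_CURRENCY) -> MetabolicModel:
    """Mark metabolites as currency so scoring views exclude them.

    Associations are kept intact (original pathway membership counts remain
    reportable); ids absent from the model are ignored with a logged count.
    Idempotent.
    """
    currency = set(currency_list)
    unknown = currency - set(model.metabolites)
    if unknown:
        logger.warning("remove_currency: %d listed ids absent from model", len(unknown))
    return replace(model, currency=frozenset(model.currency | (currency & set(model.metabolites))))


def write_model(model: MetabolicModel, gene_metabolite_path, metabolite_pathway_path) -> None:
    """Write canonicalized (sorted, deduplicated) association tables."""
    gm = pd.DataFrame(sorted(model.gene_metabolite), columns=["gene_id", "metabolite_id"])
    mp = pd.DataFrame(sorted(model.metabolite_pathway), columns=["metabolite_id", "pathway_id"])
    gm.to_csv(gene_metabolite_path, sep="\t", index=False)
    mp.to_csv(metabolite_pathway_path, sep="\t", index=False)


def read_currency_list(path) -> frozenset[str]:
    """One metabolite id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)
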