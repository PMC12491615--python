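"""Comparison-cohort screen for African-derived candidate genes.

Candidate genes are interrogated for PPVs in non-African cases and
healthy aged controls; a gene is dropped from the African-relevant list
only when the comparison population carries a strictly higher aggregate
PPV burden.  Genes without any comparison-cohort PPV are flagged
conserved, and variants shared across ancestries are reported without
triggering exclusion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .classification import ClassifiedVariant
from .errors import ConfigError, UndefinedFrequencyError
from .types import GenotypeCall

log = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class GeneBurden:
    """Aggregate PPV burden of one gene in one cohort."""

    gene: str
    cohort: str
    n_unique_ppvs: int
    carrier_count: int
    aggregate_maf: float  # summed PPV allele counts over 2n
    mean_variant_maf: float = 0.0

    @property
    def conserved(self) -> bool:
        return self.n_unique_ppvs == 0


def gene_burden(
    classified: Iterable[ClassifiedVariant],
    calls: Iterable[GenotypeCall],
    cohort: str,
    n_patients: int,
    genes: Optional[Iterable[str]] = None,
) -> dict[str, GeneBurden]:
    """Per-gene PPV counts, unique carriers and aggregate MAF in one cohort.

    ``genes`` optionally forces zero-burden (conserved) entries for
    candidate genes with no PPV in this cohort.
    """
    if n_patients < 1:
        raise UndefinedFrequencyError(f"empty cohort {cohort!r}")
    ppvs = {cv.key: cv for cv in classified if cv.is_ppv_class}
    by_key: dict[str, list[GenotypeCall]] = {}
    for call in calls:
        if call.key in ppvs and call.allele_count > 0:
            by_key.setdefault(call.key, []).append(call)

    per_gene: dict[str, dict] = {}
    for g in genes or ():
        per_gene[g.upper()] = {"keys": set(), "carriers": set(), "ac": 0, "mafs": []}
    for key, cv in ppvs.items():
        gene = (cv.variant.gene or "").upper()
        slot = per_gene.setdefault(
            gene, {"keys": set(), "carriers": set(), "ac": 0, "mafs": []}
        )
        carriers = by_key.get(key, [])
        if not carriers:
            continue
        ac = sum(c.allele_count for c in carriers)
        slot["keys"].add(key)
        slot["carriers"].update(c.patient_id for c in carriers)
        slot["ac"] += ac
        slot["mafs"].append(ac / (2 * n_patients))

    return {
        gene: GeneBurden(
            gene=gene,
            cohort=cohort,
            n_unique_ppvs=len(slot["keys"]),
            carrier_count=len(slot["carriers"]),
            aggregate_maf=slot["ac"] / (2 * n_patients),
            mean_variant_maf=(sum(slot["mafs"]) / len(slot["mafs"])) if slot["mafs"] else 0.0,
        )
        for gene, slot in per_gene.items()
    }


@dataclass(frozen=True, slots=True)
class GeneScreenDecision:
    gene: str
    keep: bool
    conserved_in: tuple[str, ...] = ()
    excluded_by: Optional[str] = None  # comparison cohort that tripped the rule


def gene_exclusion_screen(
    african: Mapping[str, GeneBurden],
    comparisons: Sequence[Mapping[str, GeneBurden]],
    metric: str = "sum",
) -> dict[str, GeneScreenDecision]:
    """Drop genes whose PPV burden is strictly higher in a comparison cohort.

    ``metric`` selects the aggregation behind "overall MAF": ``sum``
    (gene-level summed allele counts over 2n, population-size invariant)
    or ``mean`` (mean per-variant MAF).  Equal burdens keep the gene;
    each comparison cohort is screened independently.
    """
    if metric not in ("sum", "mean"):
        raise ConfigError(f"burden metric must be sum/mean, got {metric!r}")
    value = (
        (lambda b: b.aggregate_maf) if metric == "sum" else (lambda b: b.mean_variant_maf)
    )
    for comp in comparisons:
        for gene in comp:
            if gene not in african:
                log.warning(
                    "gene %s present in comparison cohort but absent from the "
                    "African candidate list; ignored",
                    gene,
                )
    decisions = {}
    for gene, burden in african.items():
        excluded_by = None
        conserved = []
        for comp in comparisons:
            cb = comp.get(gene)
            if cb is None or cb.conserved:
                if cb is not None:
                    conserved.append(cb.cohort)
                continue
            if value(cb) > value(burden):
                excluded_by = cb.cohort
                break
        decisions[gene] = GeneScreenDecision(
            gene=gene,
            keep=excluded_by is None,
            conserved_in=tuple(conserved),
            excluded_by=excluded_by,
        )
    return decisions


def shared_variant_report(
    african: Iterable[ClassifiedVariant],
    comparison_freqs: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Table of African PPVs also seen in comparison cohorts.

    ``comparison_freqs`` maps cohort name -> {variant key -> MAF}.
    Singleton-scale presence in a comparison cohort is annotation only
    and never an exclusion.
    """
    rows = []
    for cv in african:
        if not cv.is_ppv_class:
            continue
        hit = {
            cohort: freqs[cv.key]
            for cohort, freqs in comparison_freqs.items()
            if freqs.get(cv.key, 0.0) > 0.0
        }
        if not hit:
            continue
        row = {
            "key": cv.key,
            "gene": cv.variant.gene,
            "class": cv.cls,
        }
        for cohort in comparison_freqs:
            row[f"maf_{cohort.lower()}"] = hit.get(cohort, 0.0)
        rows.append(row)
    cols = ["key", "gene", "class"] + [f"maf_{c.lower()}" for c in comparison_freqs]
    return pd.DataFrame(rows, columns=cols)
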