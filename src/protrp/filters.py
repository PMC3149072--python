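"""Filter cascade for secreted proline-rich TR proteins.

Pure predicates over detected TR domains and their parent annotations:
proline content of the consensus, the TR-Module length rule, the
secretion-signal and GPI-anchor gates on external predictor scores, and
the clusterability rule.  All thresholds are inclusive where the rule
says "at least" / "minimum".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .seqio import SecretionAnnotation
from .trdetect import TRDomain

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Thresholds of the filter cascade (defaults are the published
    screen's values)."""

    pro_min_fraction: float = 0.20
    module_abs_len: int = 100
    module_rel_len: int = 50
    module_rel_fraction: float = 1.0 / 3.0
    sp_hmm_min: float = 0.7
    gpi_min_specificity: float = 99.5
    min_cluster_period: int = 4

    def __post_init__(self) -> None:
        for name in ("pro_min_fraction", "module_rel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


_DEFAULTS = FilterParams()


def is_pro_rich(domain: TRDomain, params: FilterParams = _DEFAULTS) -> bool:
    """True iff the consensus has at least ``pro_min_fraction`` proline."""
    return domain.proline_fraction >= params.pro_min_fraction


def is_tr_module(domain_len: int, protein_len: int,
                 params: FilterParams = _DEFAULTS) -> bool:
    """TR-Module rule: the domain spans >= 100 aa, or >= 50 aa and at
    least one third of its parent protein."""
    if not 0 < domain_len <= protein_len:
        raise ValueError("require 0 < domain_len <= protein_len")
    return (domain_len >= params.module_abs_len
            or (domain_len >= params.module_rel_len
                and domain_len >= protein_len * params.module_rel_fraction))


def passes_secretion(ann: SecretionAnnotation | None,
                     params: FilterParams = _DEFAULTS) -> bool:
    """Secretion gate: HMM signal-peptide probability >= 0.7 OR all five
    neural-network components called 'Yes'.

    A missing annotation is treated as not secreted (logged).
    """
    if ann is None:
        logger.warning("missing secretion annotation: treated as "
                       "not secreted")
        return False
    return (ann.hmm_sp_probability >= params.sp_hmm_min
            or all(ann.nn_components_yes))


def is_gpi_anchored(ann: SecretionAnnotation | None,
                    params: FilterParams = _DEFAULTS) -> bool:
    """GPI-anchor gate: prediction specificity >= 99.5; absent -> False."""
    if ann is None or ann.gpi_specificity is None:
        return False
    return ann.gpi_specificity >= params.gpi_min_specificity


def is_clusterable(domain: TRDomain,
                   params: FilterParams = _DEFAULTS) -> bool:
    """Clusterability: period above the degenerate range (> 3) and a
    consensus free of 'X', stop, and gap characters."""
    if domain.period < params.min_cluster_period:
        return False
    return not any(c in domain.consensus for c in "X*-")


def canonical_consensus(consensus: str) -> str:
    """Lexicographically smallest cyclic rotation (phase-insensitive
    canonical form used for de-duplication)."""
    from .autosome_tr import canonical_rotation

    return canonical_rotation(consensus)


def dedup_canonical(domains: list[TRDomain]) -> list[TRDomain]:
    """Unique TR domains by cyclically canonicalized consensus; the first
    occurrence of each motif is kept."""
    seen: set[str] = set()
    out = []
    for d in domains:
        key = canonical_consensus(d.consensus)
        if key not in seen:
            seen.add(key)
            out.append(d)
    return out


def filter_report(counts: dict[str, int]) -> pd.DataFrame:
    """Survivor counts per cascade stage as a table."""
    return pd.DataFrame(
        {"stage": list(counts), "survivors": list(counts.values())})
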