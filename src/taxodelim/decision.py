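"""Delimitation decision engine.

Combines the evidence produced by the other modules into a
synonymize / retain_distinct / inconclusive verdict for one candidate
pair, in a fixed order:

1. A clear rejection of the intraspecific IBD model retains the pair
   as distinct species outright.
2. Congruence with intraspecific IBD synonymizes.
3. If the IBD test is inconclusive, any proxy for a lack of genomic
   independence synonymizes: absence of reciprocal monophyly, admixed
   individuals, or gdi below the synonymy threshold (gdi is
   synonymize-only evidence, never confirmation).
4. Otherwise the pair is retained only if at least one additional
   taxonomic character (morphometry, climatic niche, reproductive
   schedule, acoustics) shows substantial differentiation relative to
   benchmark bands, with an analyst attestation that the difference is
   not attributable to plasticity or ecological flexibility; absence of
   such data leaves the pair inconclusive.

Every fired rule is recorded so a decision can be audited and replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from taxodelim.divergence import GDI_SYNONYMY_THRESHOLD, GdiEstimate
from taxodelim.ibdtest import IBDVerdict, MorphoIBDResult
from taxodelim.overlap import OverlapResult
from taxodelim.seasonality import SeasonalReport


@dataclass
class BenchmarkBand:
    """95% CI band of a benchmark differentiation / overlap value."""

    low: float
    high: float


@dataclass
class EvidenceBundle:
    pair: tuple[str, str]
    ibd_verdict: IBDVerdict
    monophyly: Optional[dict] = None  # from reciprocal_monophyly
    admixed_individuals: Optional[list] = None
    gdi: Optional[GdiEstimate] = None
    morpho_ibd: Optional[MorphoIBDResult] = None
    morpho_overlap: Optional[OverlapResult] = None
    morpho_benchmark: Optional[BenchmarkBand] = None  # differentiation band
    niche_d: Optional[float] = None
    niche_d_ci: Optional[tuple[float, float]] = None
    niche_benchmark: Optional[BenchmarkBand] = None  # overlap (D) band
    repro: Optional[SeasonalReport] = None
    acoustic_overlap: Optional[OverlapResult] = None
    acoustic_benchmark: Optional[BenchmarkBand] = None


@dataclass
class DecisionConfig:
    gdi_threshold: float = GDI_SYNONYMY_THRESHOLD
    repro_analyst_flag: Optional[bool] = None  # analyst-attested asynchrony
    acoustic_analyst_flag: Optional[bool] = None
    attribution_confirmed: bool = True  # differentiation not attributable to plasticity etc.
    inconclusive_leans_synonymize: bool = False


@dataclass
class DelimitationDecision:
    pair: tuple[str, str]
    verdict: str  # synonymize | retain_distinct | inconclusive
    fired_rules: list[str] = field(default_factory=list)
    evidence_considered: list[str] = field(default_factory=list)


def _morpho_differentiated(bundle: EvidenceBundle) -> bool:
    """Morphometric differentiation counts only when morphometric
    variation is NOT explained by intraspecific IBD and the
    differentiation CI sits above the benchmark band."""
    if bundle.morpho_overlap is None or bundle.morpho_benchmark is None:
        return False
    if bundle.morpho_ibd is not None and bundle.morpho_ibd.classification == "fits_intraspecific_IBD":
        return False
    return bundle.morpho_overlap.ci_low > bundle.morpho_benchmark.high


def _niche_differentiated(bundle: EvidenceBundle) -> bool:
    if bundle.niche_d_ci is None or bundle.niche_benchmark is None:
        return False
    return bundle.niche_d_ci[1] < bundle.niche_benchmark.low


def delimit_pair(bundle: EvidenceBundle, config: DecisionConfig | None = None) -> DelimitationDecision:
    """Apply the staged delimitation workflow to one evidence bundle."""
    config = config or DecisionConfig()
    if bundle.ibd_verdict is None:
        raise ValueError("missing mandatory evidence: ibd_verdict")
    fired: list[str] = []
    considered = ["ibd"]

    v = bundle.ibd_verdict.verdict
    if v == "reject_intraspecific":
        fired.append("ibd.reject_intraspecific -> retain_distinct")
        return DelimitationDecision(bundle.pair, "retain_distinct", fired, considered)
    if v == "congruent_intraspecific":
        fired.append("ibd.congruent_intraspecific -> synonymize")
        return DelimitationDecision(bundle.pair, "synonymize", fired, considered)
    fired.append("ibd.inconclusive -> continue")

    # proxies for lack of genomic independence (synonymize-only)
    if bundle.monophyly is not None:
        considered.append("monophyly")
        if not bundle.monophyly.get("joint", True):
            fired.append("monophyly.absent -> synonymize")
            return DelimitationDecision(bundle.pair, "synonymize", fired, considered)
    if bundle.admixed_individuals is not None:
        considered.append("admixture")
        if len(bundle.admixed_individuals) > 0:
            fired.append("admixture.present -> synonymize")
            return DelimitationDecision(bundle.pair, "synonymize", fired, considered)
    if bundle.gdi is not None:
        considered.append("gdi")
        if bundle.gdi.mean < config.gdi_threshold:
            fired.append(
                f"gdi.mean {bundle.gdi.mean:.3f} < {config.gdi_threshold} -> synonymize"
            )
            return DelimitationDecision(bundle.pair, "synonymize", fired, considered)

    # additional taxonomic characters
    diff_found = []
    if bundle.morpho_overlap is not None:
        considered.append("morphometry")
        if _morpho_differentiated(bundle):
            diff_found.append("morphometry")
    if bundle.niche_d is not None:
        considered.append("niche")
        if _niche_differentiated(bundle):
            diff_found.append("niche")
    if bundle.repro is not None:
        considered.append("reproduction")
        if config.repro_analyst_flag:
            diff_found.append("reproduction")
    if bundle.acoustic_overlap is not None:
        considered.append("acoustics")
        if (
            bundle.acoustic_benchmark is not None
            and bundle.acoustic_overlap.ci_low > bundle.acoustic_benchmark.high
            and config.acoustic_analyst_flag
        ):
            diff_found.append("acoustics")

    if diff_found and config.attribution_confirmed:
        fired.append(f"additional_character.differentiated ({', '.join(diff_found)}) -> retain_distinct")
        return DelimitationDecision(bundle.pair, "retain_distinct", fired, considered)
    if diff_found and not config.attribution_confirmed:
        fired.append("additional_character.differentiated but attribution unconfirmed -> inconclusive")
        return DelimitationDecision(bundle.pair, "inconclusive", fired, considered)

    if config.inconclusive_leans_synonymize and len(considered) > 1:
        fired.append("no differentiation in available characters -> synonymize (configured lean)")
        return DelimitationDecision(bundle.pair, "synonymize", fired, considered)
    fired.append("no substantial differentiation demonstrated -> inconclusive")
    return DelimitationDecision(bundle.pair, "inconclusive", fired, considered)
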