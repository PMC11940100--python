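"""Multi-predictor candidate merging and exclusion-criteria triage.

Stability predictors (e.g. PROSS, FireProt 2.0, ABAUCS) each emit a table
of candidate point mutations. This module merges those tables at the site
level and applies three exclusion criteria, in order:

  i.   consensus — sites proposed by fewer than ``min_predictor_support``
       predictors are excluded;
  ii.  catalytic proximity — sites within ``distance_cutoff`` (A, heavy-atom
       minimum distance) of any residue of the user-supplied catalytic
       centre are excluded;
  iii. critical interactions — a substitution is excluded when the
       wild-type side chain participates in a hydrogen bond or salt bridge
       and the new residue lacks the donor/acceptor/charge capability to
       sustain it (capability tables in :mod:`thermotriage._chem`).

Candidates that survive all three criteria are "kept"; excluded candidates
record the first criterion they failed, with evidence. A separate ranking
step orders experimentally characterized single variants by residual
activity subject to a relative-activity floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import _chem
from .interactions import GeometryConfig, Interaction, detect_hbonds, detect_salt_bridges
from .structure import (
    MissingResidueError,
    Mutation,
    ResidueKey,
    Structure,
    format_residue_key,
    min_distance,
)


@dataclass(frozen=True)
class PredictorCandidate:
    predictor: str
    mutation: Mutation
    score: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.predictor:
            raise ValueError("predictor name must be non-empty")


@dataclass
class SiteCandidate:
    """All proposals for one position, aggregated across predictors."""

    position: int
    wt_aa: str
    substitutions: list[Mutation]
    predictors: set[str]

    @property
    def consensus_count(self) -> int:
        return len(self.predictors)


@dataclass
class TriageConfig:
    catalytic_residues: set[ResidueKey | str] = field(default_factory=set)
    distance_cutoff: float = 5.0
    min_predictor_support: int = 2
    critical_interactions: list[Interaction] | None = None
    capability_rule_enabled: bool = True
    flag_only: bool = False  # criterion iii marks instead of excluding
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if self.min_predictor_support < 1:
            raise ValueError("min_predictor_support must be >= 1")


@dataclass
class CandidateVerdict:
    mutation: Mutation
    consensus_count: int
    supporting_predictors: tuple[str, ...]
    criterion_i_pass: bool
    criterion_ii_pass: bool
    criterion_iii_pass: bool
    min_distance_to_catalytic: float | None
    implicated_interactions: tuple[Interaction, ...]
    final_status: str  # "kept" | "excluded(criterion_<x>)" | "kept(flagged_iii)"

    @property
    def kept(self) -> bool:
        return self.final_status.startswith("kept")


@dataclass
class TriageReport:
    verdicts: list[CandidateVerdict]
    config: TriageConfig

    @property
    def kept(self) -> list[CandidateVerdict]:
        return [v for v in self.verdicts if v.kept]

    def summary(self) -> dict:
        reasons: dict[str, int] = {}
        for v in self.verdicts:
            reasons[v.final_status] = reasons.get(v.final_status, 0) + 1
        return {"n_candidates": len(self.verdicts), "n_kept": len(self.kept),
                "status_counts": reasons}


def candidates_from_table(table) -> list[PredictorCandidate]:
    """Build candidates from a tidy table (pandas DataFrame or list of
    dicts) with columns ``predictor, mutation[, score, rank]``; mutations in
    ``S67G`` notation."""
    import pandas as pd

    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    missing = {"predictor", "mutation"} - set(df.columns)
    if missing:
        raise ValueError(f"candidate table lacks columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        rank = getattr(row, "rank", None)
        out.append(PredictorCandidate(
            predictor=str(row.predictor),
            mutation=Mutation.parse(str(row.mutation)),
            score=None if score is None or pd.isna(score) else float(score),
            rank=None if rank is None or pd.isna(rank) else int(rank),
        ))
    return out


def merge_candidates(tables: list[list[PredictorCandidate]]) -> list[SiteCandidate]:
    """Group predictor proposals by position.

    consensus_count is the number of distinct predictors proposing the
    position (any substitution counts as support for the site). Duplicate
    (predictor, mutation) rows are dropped with a warning.
    """
    if not tables:
        raise ValueError("at least one predictor table is required")
    seen: set[tuple[str, str]] = set()
    sites: dict[int, SiteCandidate] = {}
    for table in tables:
        for cand in table:
            dedup_key = (cand.predictor, str(cand.mutation))
            if dedup_key in seen:
                warnings.warn(f"duplicate candidate row {dedup_key} dropped", stacklevel=2)
                continue
            seen.add(dedup_key)
            pos = cand.mutation.position
            site = sites.get(pos)
            if site is None:
                site = SiteCandidate(position=pos, wt_aa=cand.mutation.wt_aa,
                                     substitutions=[], predictors=set())
                sites[pos] = site
            elif site.wt_aa != cand.mutation.wt_aa:
                warnings.warn(
                    f"conflicting wild-type residue at position {pos}: "
                    f"{site.wt_aa} vs {cand.mutation.wt_aa}", stacklevel=2)
            if all(str(m) != str(cand.mutation) for m in site.substitutions):
                site.substitutions.append(cand.mutation)
            site.predictors.add(cand.predictor)
    return [sites[p] for p in sorted(sites)]


def _sidechain_interactions(
    s: Structure, key: ResidueKey, cfg: TriageConfig
) -> list[Interaction]:
    """Detected H-bonds/salt bridges in which the residue participates via
    a side-chain atom."""
    if cfg.critical_interactions is not None:
        pool = cfg.critical_interactions
    else:
        pool = detect_hbonds(s, cfg.geometry) + detect_salt_bridges(s, cfg.geometry)
    ks = format_residue_key(key)
    out = []
    for inter in pool:
        for res_key, atom_name in inter.partners:
            if res_key == ks and atom_name not in _chem.BACKBONE_ATOMS:
                out.append(inter)
                break
    return out


def _required_capabilities(key_str: str, inter: Interaction) -> set[str]:
    """Which capabilities the residue needs to sustain this interaction."""
    need = set()
    if inter.kind == "salt_bridge":
        if inter.donor[0] == key_str:
            need.add("positive")
        if inter.acceptor[0] == key_str:
            need.add("negative")
    else:
        if inter.donor[0] == key_str:
            need.add("donor")
        if inter.acceptor[0] == key_str:
            need.add("acceptor")
    return need


_CAPABILITY_SETS = {
    "donor": _chem.AA_SIDECHAIN_DONOR,
    "acceptor": _chem.AA_SIDECHAIN_ACCEPTOR,
    "positive": _chem.AA_POSITIVE,
    "negative": _chem.AA_NEGATIVE,
}


def _sustains(new_aa: str, capabilities: set[str]) -> bool:
    return all(new_aa in _CAPABILITY_SETS[c] for c in capabilities)


def apply_triage(
    candidates: list[SiteCandidate],
    s: Structure,
    cfg: TriageConfig,
) -> TriageReport:
    """Evaluate the three exclusion criteria for every proposed substitution.

    Criteria are evaluated in order i, ii, iii; an excluded candidate's
    status names the first criterion it failed. Criterion ii is skipped
    (passes trivially) when the catalytic residue set is empty.
    """
    catalytic: list[ResidueKey] = []
    for k in cfg.catalytic_residues:
        try:
            catalytic.append(s.residue(k).key)
        except MissingResidueError:
            raise ValueError(f"catalytic residue {k!r} not found in structure") from None

    verdicts: list[CandidateVerdict] = []
    for site in candidates:
        try:
            res = s.find_position(site.position)
            res_key = res.key
        except MissingResidueError:
            res_key = None

        pass_i = site.consensus_count >= cfg.min_predictor_support

        mindist: float | None = None
        pass_ii = True
        if catalytic and res_key is not None:
            mindist = min(min_distance(s, res_key, ck) for ck in catalytic)
            pass_ii = mindist > cfg.distance_cutoff

        implicated: tuple[Interaction, ...] = ()
        if cfg.capability_rule_enabled and res_key is not None:
            implicated = tuple(_sidechain_interactions(s, res_key, cfg))

        for mut in site.substitutions:
            pass_iii = True
            if cfg.capability_rule_enabled and implicated:
                ks = format_residue_key(res_key)
                for inter in implicated:
                    if not _sustains(mut.new_aa, _required_capabilities(ks, inter)):
                        pass_iii = False
                        break
            if not pass_i:
                status = "excluded(criterion_i)"
            elif not pass_ii:
                status = "excluded(criterion_ii)"
            elif not pass_iii:
                status = "kept(flagged_iii)" if cfg.flag_only else "excluded(criterion_iii)"
            else:
                status = "kept"
            verdicts.append(CandidateVerdict(
                mutation=mut,
                consensus_count=site.consensus_count,
                supporting_predictors=tuple(sorted(site.predictors)),
                criterion_i_pass=pass_i,
                criterion_ii_pass=pass_ii,
                criterion_iii_pass=pass_iii,
                min_distance_to_catalytic=mindist,
                implicated_interactions=implicated,
                final_status=status,
            ))
    return TriageReport(verdicts=verdicts, config=cfg)


@dataclass
class SingleVariantAssay:
    mutation: Mutation
    relative_activity: float  # % of wild type under standard assay
    residual_activity: float  # % remaining after heat challenge

    def __post_init__(self) -> None:
        if self.relative_activity < 0 or self.residual_activity < 0:
            raise ValueError("activity percentages must be non-negative")


def rank_singles(
    assays: list[SingleVariantAssay],
    relative_activity_floor: float = 90.0,
) -> list[SingleVariantAssay]:
    """Order single variants for stacking.

    Variants at or above the relative-activity floor are sorted by residual
    activity (descending), ties broken by relative activity (descending),
    then position (ascending). Variants below the floor are appended after
    the survivors in the same order (deprioritized, not dropped).
    """
    def sort_key(a: SingleVariantAssay):
        return (-a.residual_activity, -a.relative_activity, a.mutation.position)

    survivors = sorted((a for a in assays if a.relative_activity >= relative_activity_floor),
                       key=sort_key)
    deprioritized = sorted((a for a in assays if a.relative_activity < relative_activity_floor),
                           key=sort_key)
    return survivors + deprioritized
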