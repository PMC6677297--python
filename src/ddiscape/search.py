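"""Best-match search of query interfaces against template libraries,
Table-style summary statistics, and cross-library comparison."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import SignificanceModel, align_interfaces
from .datasets import DomainPairRecord, TemplateLibrary
from .scoring import AlignmentScores, ScoringParams


@dataclass
class SearchResult:
    query_id: str
    best_template_id: str | None
    scores: AlignmentScores | None
    significant: bool | None = None

    @property
    def found(self) -> bool:
        return self.best_template_id is not None


@dataclass
class SummaryStats:
    n: int
    mean_IS: float
    sd_IS: float
    mean_rmsd: float
    sd_rmsd: float
    mean_f_res: float
    sd_f_res: float
    mean_f_con: float
    sd_f_con: float
    fraction_significant: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def best_match(
    query: DomainPairRecord,
    library: TemplateLibrary,
    params: ScoringParams | None = None,
    significance: SignificanceModel | None = None,
) -> SearchResult:
    """Align the query interface against every template; the best match is
    the template with the maximum IS-score (ties break to the first template
    id in sorted order)."""
    if not library.templates:
        return SearchResult(query_id=query.pair_id, best_template_id=None,
                            scores=None)
    best_id, best_scores = None, None
    for tmpl in sorted(library.templates, key=lambda t: t.pair_id):
        _, scores = align_interfaces(query.interface, tmpl.interface, params)
        if best_scores is None or scores.IS_score > best_scores.IS_score:
            best_id, best_scores = tmpl.pair_id, scores
    significant = None
    if significance is not None:
        best_scores.p_value = significance.p_value(best_scores.IS_score)
        significant = best_scores.p_value < significance.alpha
    return SearchResult(query_id=query.pair_id, best_template_id=best_id,
                        scores=best_scores, significant=significant)


def run_dataset_search(
    records: list[DomainPairRecord],
    library_builder,
    params: ScoringParams | None = None,
    significance: SignificanceModel | None = None,
) -> tuple[list[SearchResult], list[str]]:
    """One best-match result per query with a nonempty library; queries whose
    libraries come back empty are reported separately (second return value),
    mirroring the exclusion of template-less queries from the statistics."""
    results, skipped = [], []
    for rec in records:
        library = library_builder(rec)
        if not library.templates:
            skipped.append(rec.pair_id)
            continue
        results.append(best_match(rec, library, params, significance))
    return results, skipped


def summarize(results: list[SearchResult]) -> SummaryStats:
    """Sample means and SDs (n-1 convention) of the best-match scores."""
    found = [r for r in results if r.found]
    if not found:
        raise ValueError("no results to summarize")

    def stats(vals):
        arr = np.asarray(vals, float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return float(np.mean(arr)), sd

    mean_is, sd_is = stats([r.scores.IS_score for r in found])
    mean_rmsd, sd_rmsd = stats([r.scores.rmsd for r in found])
    mean_fres, sd_fres = stats([r.scores.f_res for r in found])
    mean_fcon, sd_fcon = stats([r.scores.f_con for r in found])
    flags = [r.significant for r in found if r.significant is not None]
    frac = sum(flags) / len(flags) if flags else None
    return SummaryStats(
        n=len(found),
        mean_IS=mean_is, sd_IS=sd_is,
        mean_rmsd=mean_rmsd, sd_rmsd=sd_rmsd,
        mean_f_res=mean_fres, sd_f_res=sd_fres,
        mean_f_con=mean_fcon, sd_f_con=sd_fcon,
        fraction_significant=frac,
    )


@dataclass
class CrossSearchReport:
    per_library: dict[str, SummaryStats]
    per_query: pd.DataFrame = field(repr=False, default=None)


def cross_search(
    queries: list[DomainPairRecord],
    libraries: dict[str, "callable"],
    params: ScoringParams | None = None,
    significance: SignificanceModel | None = None,
) -> CrossSearchReport:
    """Search the same queries against several libraries (e.g. intra, inter,
    merged) and compare. For every query the merged library's best IS-score
    must equal the max over its constituents — checked when a 'merged'
    library is present alongside others."""
    per_library: dict[str, SummaryStats] = {}
    rows: dict[str, dict] = {}
    for name, builder in libraries.items():
        results, skipped = run_dataset_search(queries, builder, params,
                                              significance)
        if results:
            per_library[name] = summarize(results)
        for r in results:
            rows.setdefault(r.query_id, {})[name] = r.scores.IS_score
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if "merged" in df.columns:
        parts = [c for c in df.columns if c != "merged"]
        if parts:
            best_parts = df[parts].max(axis=1)
            bad = df["merged"] + 1e-9 < best_parts
            if bad.any():
                raise AssertionError(
                    f"merged library scored below a constituent for "
                    f"{list(df.index[bad])}"
                )
    return CrossSearchReport(per_library=per_library, per_query=df)


def results_table(results: list[SearchResult]) -> pd.DataFrame:
    """One row per query: template, IS-score, RMSD, N_a, f_res, f_con, p."""
    rows = []
    for r in results:
        s = r.scores
        rows.append(
            {
                "query": r.query_id,
                "template": r.best_template_id,
                "IS_score": s.IS_score if s else np.nan,
                "rmsd": s.rmsd if s else np.nan,
                "N_a": s.N_a if s else 0,
                "f_res": s.f_res if s else np.nan,
                "f_con": s.f_con if s else np.nan,
                "p_value": s.p_value if s else np.nan,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def paired_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Reporting utility: paired t-test between two score sets."""
    from scipy.stats import ttest_rel

    res = ttest_rel(np.asarray(scores_a, float), np.asarray(scores_b, float))
    return float(res.statistic), float(res.pvalue)
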