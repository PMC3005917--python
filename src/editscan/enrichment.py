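"""GO-term enrichment of edited gene sets by one-sided hypergeometric tests.

For each annotation term with at least one edited gene, the upper-tail
hypergeometric probability of drawing at least the observed number of
term-bearing genes is computed against the whole background, then corrected
for multiple testing (Bonferroni by default, Benjamini-Hochberg optionally).
No GO-graph propagation is applied: the gene->term map is used as given.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    n_background: int
    n_background_with_term: int
    n_edited: int
    n_edited_with_term: int
    p_raw: float
    p_corrected: float

    @property
    def pct_all(self) -> float:
        return self.n_background_with_term / self.n_background

    @property
    def pct_edited(self) -> float:
        return self.n_edited_with_term / self.n_edited


def hypergeom_enrich(
    edited_genes: Iterable[str],
    background_genes: Iterable[str],
    go_map: Mapping[str, Iterable[str]],
    *,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Test every term observed among edited genes for over-representation.

    ``p_raw = P[X >= k]`` with X hypergeometric(N=background, K=term genes,
    n=edited). Correction is over the number of tested terms. Results are
    sorted by corrected then raw p-value.
    """
    edited = set(edited_genes)
    background = set(background_genes)
    if not edited:
        raise ValueError("empty edited gene set")
    if not edited <= background:
        raise ValueError("edited genes must be a subset of the background")
    term_background: dict[str, int] = {}
    term_edited: dict[str, int] = {}
    for gene in background:
        for term in go_map.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in edited:
                term_edited[term] = term_edited.get(term, 0) + 1
    tested = sorted(term_edited)
    if not tested:
        return []
    N, n = len(background), len(edited)
    p_raw = [
        float(hypergeom.sf(term_edited[t] - 1, N, term_background[t], n))
        for t in tested
    ]
    if correction == "bonferroni":
        p_corr = [min(1.0, p * len(tested)) for p in p_raw]
    elif correction in ("fdr_bh", "bh"):
        p_corr = list(multipletests(p_raw, method="fdr_bh")[1])
    else:
        raise ValueError(f"unknown correction {correction!r}")
    results = [
        EnrichmentResult(
            term_id=t,
            n_background=N,
            n_background_with_term=term_background[t],
            n_edited=n,
            n_edited_with_term=term_edited[t],
            p_raw=p,
            p_corrected=pc,
        )
        for t, p, pc in zip(tested, p_raw, p_corr)
    ]
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term_id))
    return results


def flag_significant(
    results: Sequence[EnrichmentResult], alpha: float = 1.0e-7
) -> list[EnrichmentResult]:
    """Results with corrected p strictly below ``alpha``."""
    return [r for r in results if r.p_corrected < alpha]
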