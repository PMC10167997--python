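"""Detection of horizontal transposon transfer from the dS-CUB contrast.

For each species pair, the synonymous divergence of vertically inherited
reference genes is regressed on their codon usage bias (mean ENC of the two
copies). A TE family whose between-species dS falls significantly below the
value this regression predicts at the TE's own ENC is flagged as a putative
horizontal transfer: vertical inheritance cannot make a sequence look younger
than the host divergence, while a recent transfer can.

The test is a one-sided prediction-interval t-test on the OLS fit of
log dS ~ mean ENC (Student t with n-2 df, prediction-interval standard
error at the TE's ENC). The log scale is the default because dS residuals
are right-skewed (the divergence correction stretches the upper tail),
which makes the linear-scale test conservative in calibration simulations;
the linear scale remains available via ``scale="linear"``. Multiple testing
is handled by Holm correction within each TE family across its species
pairs. All choices are recorded in output metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CodonAlignment, RunConfig
from .divergence_stats import GeneStats, pair_stats, percent_identity

logger = logging.getLogger("httflow")

MIN_REFERENCE_GENES = 5


class InsufficientReferenceError(ValueError):
    """Fewer than the minimum usable reference genes for a species pair."""


@dataclass
class ReferenceSet:
    """Reference gene alignments (target: 30 single-copy orthologs).

    Caches per-pair :class:`GeneStats` tables; saturated genes are retained
    in the table with a flag and dropped per pair at model-fitting time.
    """

    genes: list[CodonAlignment]
    _cache: dict[tuple[str, str], list[GeneStats]] = field(
        default_factory=dict, repr=False
    )

    def pair_table(self, sp1: str, sp2: str) -> list[GeneStats]:
        key = (sp1, sp2) if sp1 <= sp2 else (sp2, sp1)
        if key not in self._cache:
            table = []
            for gene in self.genes:
                if sp1 not in gene.sequences or sp2 not in gene.sequences:
                    continue
                table.append(pair_stats(gene, *key))
            self._cache[key] = table
        return self._cache[key]

    @property
    def species(self) -> list[str]:
        out: set[str] = set()
        for g in self.genes:
            out.update(g.species)
        return sorted(out)


#: floor applied to dS before taking logs (identical copies give dS = 0)
_DS_FLOOR = 1e-4


@dataclass
class ReferenceModel:
    """OLS fit of reference-gene (log) dS on mean ENC for one species pair.

    ``slope`` and ``intercept`` live on the regression scale (log dS by
    default); :meth:`predict` always returns a dS on the natural scale.
    """

    species_pair: tuple[str, str]
    slope: float
    intercept: float
    resid_se: float
    n: int
    x_mean: float
    sxx: float
    scale: str = "log"  # "log" | "linear"

    def linear_predictor(self, enc: float) -> float:
        return self.intercept + self.slope * enc

    def predict(self, enc: float) -> float:
        """Expected dS at codon usage bias ``enc`` (natural scale)."""
        pred = self.linear_predictor(enc)
        return math.exp(pred) if self.scale == "log" else pred

    def transform(self, ds: float) -> float:
        """Map an observed dS onto the regression scale."""
        return math.log(max(ds, _DS_FLOOR)) if self.scale == "log" else ds

    def prediction_se(self, enc: float) -> float:
        """Standard error of a new observation's deviation at ``enc``."""
        if self.sxx <= 0:
            return self.resid_se * math.sqrt(1.0 + 1.0 / self.n)
        return self.resid_se * math.sqrt(
            1.0 + 1.0 / self.n + (enc - self.x_mean) ** 2 / self.sxx
        )


@dataclass
class PairSignal:
    """Result of the dS-CUB contrast for one (TE family, species pair)."""

    family: str
    superfamily: str
    order: str
    species_pair: tuple[str, str]
    ds: float
    mean_enc: float
    expected_ds: float
    residual: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
    saturated: bool = False


def prefilter_te_candidates(
    families: list[CodonAlignment],
    min_len: int = 600,
    min_id: float = 0.90,
) -> list[tuple[CodonAlignment, tuple[str, str]]]:
    """Conservative pre-filter for recent-transfer candidates.

    A (family, species pair) passes iff both sequences carry at least
    ``min_len`` non-gap bases and their pairwise identity is at least
    ``min_id``.
    """
    out = []
    for fam in families:
        for sp1, sp2 in fam.pairs():
            a, b = fam.sequences[sp1], fam.sequences[sp2]
            if min(_ungapped_length(a), _ungapped_length(b)) < min_len:
                continue
            if percent_identity(a, b) < min_id:
                continue
            out.append((fam, (sp1, sp2)))
    return out


def _ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c in "ACGTacgt")


def fit_reference_model(
    refs: ReferenceSet, pair: tuple[str, str], scale: str = "log"
) -> ReferenceModel:
    """OLS of reference-gene (log) dS on mean ENC across unsaturated genes.

    On the default log scale, genes with dS = 0 for the pair are dropped
    (they carry no information about proportional scatter).
    """
    if scale not in {"log", "linear"}:
        raise ValueError("scale must be log|linear")
    table = [g for g in refs.pair_table(*pair) if not g.saturated]
    if scale == "log":
        table = [g for g in table if g.ds > 0]
    if len(table) < MIN_REFERENCE_GENES:
        raise InsufficientReferenceError(
            f"pair {pair}: only {len(table)} usable reference genes "
            f"(need >= {MIN_REFERENCE_GENES})"
        )
    x = np.array([g.mean_enc for g in table])
    y = np.array([g.ds for g in table])
    if scale == "log":
        y = np.log(y)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid_se = math.sqrt(fit.ssr / fit.df_resid) if fit.df_resid > 0 else 0.0
    return ReferenceModel(
        species_pair=(min(pair), max(pair)),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        resid_se=resid_se,
        n=len(table),
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        scale=scale,
    )


def vhica_test(
    model: ReferenceModel,
    te_stats: GeneStats,
    alpha: float = 0.05,
    family: str = "",
    superfamily: str = "",
    order: str = "",
) -> PairSignal:
    """One-sided test of whether a TE's dS lies below the reference trend.

    ``p = P(T_{n-2} > (predicted - observed) / SE_pred)``; a TE exactly on
    the regression line gives p = 0.5. A saturated TE dS is non-significant
    by construction and flagged.
    """
    expected = model.predict(te_stats.mean_enc)
    if te_stats.saturated or not math.isfinite(te_stats.ds):
        return PairSignal(
            family=family, superfamily=superfamily, order=order,
            species_pair=te_stats.species_pair, ds=te_stats.ds,
            mean_enc=te_stats.mean_enc, expected_ds=expected,
            residual=float("nan"), p_value=1.0, saturated=True,
        )
    se = model.prediction_se(te_stats.mean_enc)
    residual = te_stats.ds - expected
    if se <= 0:
        p = 0.0 if residual < 0 else 1.0
    else:
        tstat = (
            model.linear_predictor(te_stats.mean_enc)
            - model.transform(te_stats.ds)
        ) / se
        p = float(stats.t.sf(tstat, df=model.n - 2))
    sig = p <= alpha and residual < 0
    return PairSignal(
        family=family, superfamily=superfamily, order=order,
        species_pair=te_stats.species_pair, ds=te_stats.ds,
        mean_enc=te_stats.mean_enc, expected_ds=expected,
        residual=residual, p_value=p, p_adjusted=p, significant=sig,
    )


def run_detection(
    families: list[CodonAlignment],
    refs: ReferenceSet,
    config: RunConfig | None = None,
) -> list[PairSignal]:
    """Full detection pass: prefilter, per-pair reference fits, tests, Holm.

    Reference models are fitted once per species pair; the Holm correction
    is applied within each family across its surviving pairs. Output order
    (family, then species pair) is independent of input order.
    """
    config = config or RunConfig()
    candidates = prefilter_te_candidates(
        families, min_len=config.te_min_length, min_id=config.te_min_identity
    )
    models: dict[tuple[str, str], ReferenceModel | None] = {}
    signals: list[PairSignal] = []
    for fam, pair in candidates:
        key = (min(pair), max(pair))
        if key not in models:
            try:
                models[key] = fit_reference_model(refs, key)
            except InsufficientReferenceError as exc:
                logger.warning("skipping pair %s: %s", key, exc)
                models[key] = None
        model = models[key]
        if model is None:
            continue
        te = pair_stats(fam, *key)
        signals.append(
            vhica_test(
                model, te, alpha=config.alpha,
                family=fam.id,
                superfamily=fam.annotation.get("superfamily", ""),
                order=fam.annotation.get("order", ""),
            )
        )
    # Holm within family across pairs
    by_family: dict[str, list[PairSignal]] = {}
    for s in signals:
        by_family.setdefault(s.family, []).append(s)
    for fam_signals in by_family.values():
        pvals = [s.p_value for s in fam_signals]
        reject, p_adj, _, _ = multipletests(
            pvals, alpha=config.alpha, method="holm"
        )
        for s, r, pa in zip(fam_signals, reject, p_adj):
            s.p_adjusted = float(pa)
            s.significant = bool(r) and (
                math.isfinite(s.residual) and s.residual < 0
            )
    signals.sort(key=lambda s: (s.family, s.species_pair))
    return signals


def signals_frame(signals: list[PairSignal]) -> pd.DataFrame:
    """Signals as a TSV-ready table."""
    rows = [
        [
            s.family, s.superfamily, s.order, s.species_pair[0],
            s.species_pair[1], s.ds, s.mean_enc, s.expected_ds, s.residual,
            s.p_value, s.p_adjusted, s.significant, s.saturated,
        ]
        for s in signals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "family", "superfamily", "order", "sp1", "sp2", "ds", "mean_enc",
            "expected_ds", "residual", "p", "p_adj", "significant", "saturated",
        ],
    )


def signals_from_frame(df: pd.DataFrame) -> list[PairSignal]:
    """Inverse of :func:`signals_frame` (round-trips through TSV)."""
    out = []
    for r in df.itertuples():
        out.append(
            PairSignal(
                family=str(r.family), superfamily=str(r.superfamily),
                order=str(r.order), species_pair=(str(r.sp1), str(r.sp2)),
                ds=float(r.ds), mean_enc=float(r.mean_enc),
                expected_ds=float(r.expected_ds), residual=float(r.residual),
                p_value=float(r.p), p_adjusted=float(r.p_adj),
                significant=bool(r.significant), saturated=bool(r.saturated),
            )
        )
    return out
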