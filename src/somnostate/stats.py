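"""Trend models and topographic randomization statistics.

Linear mixed-effects models with a random intercept per patient relate each
microstate quantifier or state space descriptor to anaesthesia duration,
suppression status and subsequent postoperative delirium (POD). Descriptor
models carry the three-way interaction duration x suppression x POD;
quantifier models stack the four microstate classes in long format and
expand it to the four-way interaction with class. All models adjust for
age, sex, MMSE band, ASA band, surgical site, anaesthetic type and
randomization arm, with reference levels no POD, no suppression, duration 0.

Per-cell slopes of anaesthesia duration (e.g. Supp+|POD+) are linear
combinations of the fitted coefficients; the reference cell's slope is the
bare duration coefficient. Topographic differences between conditions are
tested with a randomization test (TANOVA): the effect statistic is the GFP
of the difference of cell-mean topographies (root-mean GFP of the
double-centred effect maps for multi-level effects), and the null is built
by shuffling condition labels within subjects (within effects) or group
labels across subjects (between effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sstats

from somnostate.core import DesignError
from somnostate.microstates import gfp

COVARIATES = (
    "age", "sex", "mmse_band", "asa_band", "surgical_site", "anaesthetic", "randomization",
)

RESPONSES_QUANTIFIER = ("duration_ms", "occurrence", "gfp")
RESPONSES_DESCRIPTOR = ("sigma", "phi", "omega")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, interaction order and adjustment set."""

    response: str
    kind: str                       # 'quantifier' (4-way) or 'descriptor' (3-way)
    covariates: tuple[str, ...] = COVARIATES
    random_slopes: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("quantifier", "descriptor"):
            raise ValueError("kind must be 'quantifier' or 'descriptor'")

    @property
    def formula(self) -> str:
        inter = "anaesthesia_duration * suppression * pod"
        if self.kind == "quantifier":
            inter += " * microstate"
        rhs = inter
        if self.covariates:
            rhs += " + " + " + ".join(self.covariates)
        return f"{self.response} ~ {rhs}"


@dataclass
class ModelResult:
    spec: ModelSpec
    coefficients: pd.DataFrame       # estimate, se, ci_low, ci_high, p
    term_tests: pd.DataFrame         # Wald chi2 per model term
    cov_fe: pd.DataFrame
    random_effects_var: float
    converged: bool
    singular: bool
    results: object = field(repr=False, default=None)   # statsmodels results
    duration_range: tuple[float, float] = (0.0, 0.0)


def prepare_table(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Join interval records with patient covariates for modelling.

    Renames ``mean_time`` to ``anaesthesia_duration`` (minutes) and encodes
    suppression/POD as 0/1 integers so the reference levels are no
    suppression / no POD / duration 0.
    """
    df = records.merge(meta, on="patient_id", how="inner", validate="many_to_one")
    df = df.rename(columns={"mean_time": "anaesthesia_duration"})
    df["suppression"] = df["suppression"].astype(int)
    df["pod"] = df["pod"].astype(int)
    for col in ("sex", "mmse_band", "asa_band", "surgical_site", "anaesthetic", "randomization"):
        if col in df:
            df[col] = df[col].astype("category")
    if "class_index" in df and "microstate" not in df:
        df["microstate"] = pd.Categorical.from_codes(
            df["class_index"].astype(int), categories=["A", "B", "C", "D"]
        )
    return df


def _check_design(df: pd.DataFrame, spec: ModelSpec) -> None:
    if df["patient_id"].nunique() < 2:
        raise DesignError("between-subject modelling needs >= 2 patients")
    for flag in ("pod",):
        counts = df.groupby(flag, observed=True)["patient_id"].nunique()
        if len(counts) < 2 or (counts < 2).any():
            raise DesignError("need >= 2 patients in each POD group")
    cells = df.groupby(["pod", "suppression"], observed=True).size()
    if len(cells) < 4:
        raise DesignError(
            "empty pod x suppression cell: the interaction is unidentifiable"
        )


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """REML fit of the trend model with a random intercept per patient.

    Term significance is reported as large-sample Wald chi-square tests. A
    singular random-effects fit (patient variance collapsing to ~0) is
    flagged and the fixed effects are kept — they then coincide with the
    simple residual-variance solution.
    """
    df = table.dropna(subset=[spec.response]).copy()
    _check_design(df, spec)
    model = smf.mixedlm(spec.formula, df, groups=df["patient_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception:
            res = model.fit(reml=True, method="powell", maxiter=500)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    singular = re_var < 1e-8 * max(float(res.scale), 1e-300)
    if singular:
        warnings.warn("singular random-effects fit; variance ~ 0", stacklevel=2)

    k_fe = model.k_fe
    fe = res.fe_params
    cov_fe = res.cov_params().iloc[:k_fe, :k_fe]
    # singular fits can leave tiny negative diagonal entries in cov_params
    se = np.sqrt(np.clip(np.diag(cov_fe), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fe.values / np.where(se > 0, se, 1.0), np.nan)
    coefficients = pd.DataFrame(
        {
            "estimate": fe.values,
            "se": se,
            "ci_low": fe.values - 1.96 * se,
            "ci_high": fe.values + 1.96 * se,
            "p": 2 * sstats.norm.sf(np.abs(z)),
        },
        index=fe.index,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            term_tests = res.wald_test_terms(scalar=True).table
        except Exception:
            term_tests = pd.DataFrame()
    return ModelResult(
        spec=spec,
        coefficients=coefficients,
        term_tests=term_tests,
        cov_fe=cov_fe,
        random_effects_var=re_var,
        converged=bool(res.converged),
        singular=singular,
        results=res,
        duration_range=(
            float(df["anaesthesia_duration"].min()),
            float(df["anaesthesia_duration"].max()),
        ),
    )


def _find_param(index: pd.Index, components: set[str]) -> str:
    """Locate the coefficient whose ':'-split factor set equals ``components``."""
    for name in index:
        if set(name.split(":")) == components:
            return name
    raise KeyError(f"model has no term for {sorted(components)}")


def contrast_slopes(
    result: ModelResult,
    pod: bool,
    suppression: bool,
    microstate: str | None = None,
) -> pd.Series:
    """Slope of anaesthesia duration in one (POD, suppression)[, class] cell.

    The slope is the sum of the duration coefficient and every duration
    interaction coefficient switched on in that cell; its variance follows
    from the corresponding combination of the coefficient covariance. The
    reference cell returns exactly the bare duration coefficient (plus the
    class-interaction term away from class A in quantifier models).
    """
    idx = result.coefficients.index
    terms: list[str] = [_find_param(idx, {"anaesthesia_duration"})]

    def add(extra: set[str]) -> None:
        terms.append(_find_param(idx, {"anaesthesia_duration"} | extra))

    is_quant = result.spec.kind == "quantifier"
    if is_quant and microstate is None:
        raise ValueError("quantifier models need a microstate class for the contrast")
    if not is_quant and microstate is not None:
        raise ValueError("descriptor models have no microstate factor")

    ms_term = None
    if is_quant and microstate != "A":
        ms_term = f"microstate[T.{microstate}]"
        add({ms_term})
    if suppression:
        add({"suppression"})
        if ms_term:
            add({"suppression", ms_term})
    if pod:
        add({"pod"})
        if ms_term:
            add({"pod", ms_term})
    if suppression and pod:
        add({"suppression", "pod"})
        if ms_term:
            add({"suppression", "pod", ms_term})

    L = pd.Series(0.0, index=idx)
    L[terms] = 1.0
    est = float(L @ result.coefficients["estimate"])
    var = float(L @ result.cov_fe @ L)
    se = np.sqrt(max(var, 0.0))
    return pd.Series(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
            "p": 2 * sstats.norm.sf(abs(est) / se) if se > 0 else np.nan,
        }
    )


def contrast_table(result: ModelResult) -> pd.DataFrame:
    """All per-cell duration slopes (x class for quantifier models)."""
    rows = []
    classes = ["A", "B", "C", "D"] if result.spec.kind == "quantifier" else [None]
    for pod in (False, True):
        for supp in (False, True):
            for ms in classes:
                s = contrast_slopes(result, pod, supp, ms)
                row = dict(pod=pod, suppression=supp, **s.to_dict())
                if ms is not None:
                    row["microstate"] = ms
                rows.append(row)
    return pd.DataFrame(rows)


def predicted_trajectories(
    result: ModelResult,
    durations: np.ndarray,
    table: pd.DataFrame,
) -> pd.DataFrame:
    """Model-implied mean response over a duration grid for all four cells.

    Continuous covariates sit at their sample mean, categorical covariates
    at their reference level. The band is the 95% confidence interval of
    the fixed-effects mean. Grid points beyond the observed duration range
    are flagged ``extrapolated`` rather than refused.
    """
    res = result.results
    classes = ["A", "B", "C", "D"] if result.spec.kind == "quantifier" else [None]
    ref = {}
    for col in result.spec.covariates:
        series = table[col]
        if series.dtype.kind in "fiu":
            ref[col] = float(series.mean())
        else:
            ref[col] = series.astype("category").cat.categories[0]
    rows = []
    for pod in (0, 1):
        for supp in (0, 1):
            for ms in classes:
                for d in durations:
                    row = dict(anaesthesia_duration=float(d), suppression=supp, pod=pod, **ref)
                    if ms is not None:
                        row["microstate"] = ms
                    rows.append(row)
    grid = pd.DataFrame(rows)
    design = res.model.data.design_info
    from patsy import dmatrix

    X = np.asarray(dmatrix(design, grid))
    mean = X @ result.coefficients["estimate"].values
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, result.cov_fe.values, X), 0.0, None))
    out = grid.copy()
    out["predicted"] = mean
    out["ci_low"] = mean - 1.96 * se
    out["ci_high"] = mean + 1.96 * se
    lo, hi = result.duration_range
    out["extrapolated"] = (out["anaesthesia_duration"] < lo) | (out["anaesthesia_duration"] > hi)
    return out


# ---------------------------------------------------------------------------
# TANOVA and channel-wise t-maps
# ---------------------------------------------------------------------------

@dataclass
class TanovaResult:
    table: pd.DataFrame              # effect, observed, p, n_permutations
    n_permutations: int


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=-1, keepdims=True)
    g = np.sqrt(np.mean(maps**2, axis=-1, keepdims=True))
    g[g == 0] = 1.0
    return maps / g


def _effect_statistic(maps: np.ndarray, pod: np.ndarray, effect: tuple[str, ...]) -> float:
    """Root-mean GFP of the double-centred effect topographies.

    ``maps`` is (subjects, classes, suppression, channels); ``effect`` is a
    subset of ('class', 'supp', 'pod'). Cell means are computed over
    subjects per group, then the factorial decomposition extracts the
    requested effect by iterated marginal centring.
    """
    groups = [maps[~pod], maps[pod]] if "pod" in effect else [maps]
    # cell-mean cube: (pod_levels, classes, supp, channels)
    cube = np.stack([g.mean(axis=0) for g in groups])
    axis_of = {"pod": 0, "class": 1, "supp": 2}
    for name, ax in axis_of.items():
        marginal = cube.mean(axis=ax, keepdims=True)
        if name in effect:
            cube = cube - marginal      # centre: keep only variation along ax
        else:
            cube = marginal             # collapse: average out this factor
    g2 = np.mean(cube**2, axis=-1)      # squared GFP of each effect map
    return float(np.sqrt(np.mean(g2)))


def tanova(
    maps: np.ndarray,
    pod: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
    effects: tuple[tuple[str, ...], ...] = (
        ("class",), ("supp",), ("pod",),
        ("class", "supp"), ("class", "pod"), ("supp", "pod"),
        ("class", "supp", "pod"),
    ),
) -> TanovaResult:
    """Topographic randomization test on first-interval microstate maps.

    ``maps`` is (subjects, n_classes, 2, n_channels): one map per subject
    per class per suppression status. Maps are GFP-normalized. Within
    effects shuffle the class x suppression cell assignment within each
    subject; effects involving the between factor shuffle POD labels
    across subjects. p = (#null >= observed + 1) / (n + 1).
    """
    maps = _normalize_maps(np.asarray(maps, dtype=float))
    pod = np.asarray(pod, dtype=bool)
    if maps.ndim != 4 or maps.shape[0] != pod.size:
        raise ValueError("maps must be (subjects, classes, suppression, channels)")
    if min((~pod).sum(), pod.sum()) < 2:
        raise DesignError("need >= 2 patients per POD group for between effects")
    rng = np.random.default_rng(seed)
    n_sub, n_cls, n_sup, n_ch = maps.shape

    observed = {e: _effect_statistic(maps, pod, e) for e in effects}
    exceed = {e: 0 for e in effects}
    flat = maps.reshape(n_sub, n_cls * n_sup, n_ch)
    for _ in range(n_permutations):
        perm_within = np.empty_like(flat)
        for s in range(n_sub):
            perm_within[s] = flat[s, rng.permutation(n_cls * n_sup)]
        perm_maps = perm_within.reshape(n_sub, n_cls, n_sup, n_ch)
        perm_pod = pod[rng.permutation(n_sub)]
        for e in effects:
            use_maps = perm_maps if set(e) & {"class", "supp"} else maps
            use_pod = perm_pod if "pod" in e else pod
            if _effect_statistic(use_maps, use_pod, e) >= observed[e]:
                exceed[e] += 1
    rows = [
        dict(
            effect=" x ".join(e),
            observed=observed[e],
            p=(exceed[e] + 1) / (n_permutations + 1),
        )
        for e in effects
    ]
    return TanovaResult(table=pd.DataFrame(rows), n_permutations=n_permutations)


def channel_t_map(maps_a: np.ndarray, maps_b: np.ndarray, paired: bool = True) -> np.ndarray:
    """Per-electrode t statistic comparing two map samples."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("channel counts differ")
    if paired:
        if a.shape != b.shape or a.shape[0] < 2:
            raise DesignError("paired comparison needs >= 2 matched subjects")
        diff = a - b
        if not diff.any():
            return np.zeros(a.shape[1])
        t, _ = sstats.ttest_rel(a, b, axis=0)
    else:
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise DesignError("need >= 2 maps per condition")
        t, _ = sstats.ttest_ind(a, b, axis=0)
    return np.nan_to_num(np.asarray(t))
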