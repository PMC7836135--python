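"""Two-stage multilevel moderation models with model-comparison inference.

The analysis fits, per electrode, an ordinary least-squares regression within
each participant (level 1) and then regresses the participant coefficients on
grand-mean-centered participant-level moderators (level 2).  Two analyses use
this machinery:

* the stimulation-response analysis regresses 25 Hz power (dB) on centered
  brightness codes (-2..2); its level-2 models are intercept-only, so the
  level-2 intercept of the slope model is the mean dB-per-step slope;
* the moderation analysis regresses unpleasantness ratings (Gracely Box
  Scale) on brightness and 25 Hz power simultaneously; each level-1
  coefficient (intercept, brightness slope, PSD slope) gets a level-2 model
  with menstrual pain, somatic symptoms and bladder pain as moderators.

Per-term sums of squares come from comparing the full level-2 model with the
model that deletes that single term (equivalent to Type III with 1 numerator
df); the error term is the full-model MSE.  Partial eta-squared is
``SS/(SS + df_den*MSE)`` and confidence intervals are t-based.  Exploratory
electrodes are corrected per (model, term) family with Benjamini-Hochberg
FDR; the a-priori channel (Oz) is reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "center_brightness",
    "Level1Fit",
    "fit_level1",
    "fit_level2",
    "eta_p2",
    "f_from_ss",
    "ci_from_se",
    "fdr_adjust",
    "bootstrap_corr",
    "TwoStageMLM",
    "TwoStageResults",
]

MODEL_NAMES = ("Intercept", "Brightness", "PSD")


def center_brightness(codes) -> np.ndarray:
    """Map the five ordered brightness levels to centered codes -2..2.

    Accepts any five distinct ordered levels (lux values, 1..5, or already
    centered codes) and returns -2, -1, 0, 1, 2 in the rank order of the
    input, so the sum is 0 and the sum of squares is 10.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.ndim != 1 or codes.size != 5 or len(np.unique(codes)) != 5:
        raise ValueError("expected exactly 5 distinct brightness levels")
    ranks = np.argsort(np.argsort(codes))
    return ranks - 2.0


@dataclass
class Level1Fit:
    """Within-participant OLS coefficients for one (participant, electrode)."""

    participant: str | int
    electrode: str | None
    b0: float
    b1: float
    b2: float | None
    residual_df: int


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares returning (coefs, SSE); raises on rank deficiency."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_level1(
    y,
    brightness,
    psd=None,
    participant: str | int = 0,
    electrode: str | None = None,
) -> Level1Fit:
    """OLS of one participant's five block observations.

    ``brightness`` must already be centered codes; ``psd``, if given, should
    be centered per the chosen convention.  Rank deficiency (e.g. PSD
    collinear with brightness) raises ``LinAlgError``; callers exclude the
    participant x electrode cell with a log entry.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.ones_like(y), np.asarray(brightness, dtype=float)]
    if psd is not None:
        cols.append(np.asarray(psd, dtype=float))
    X = np.column_stack(cols)
    if y.size < X.shape[1]:
        raise ValueError("need at least as many blocks as level-1 parameters")
    coef, _ = _ols(y, X)
    return Level1Fit(
        participant=participant,
        electrode=electrode,
        b0=float(coef[0]),
        b1=float(coef[1]),
        b2=float(coef[2]) if psd is not None else None,
        residual_df=int(y.size - X.shape[1]),
    )


def eta_p2(ss: float, df_den: int, mse: float) -> float:
    """Partial eta-squared ``SS / (SS + df_den * MSE)``."""
    if mse <= 0:
        raise ValueError("MSE must be positive")
    if ss < 0:
        raise ValueError("SS must be non-negative")
    return ss / (ss + df_den * mse)


def f_from_ss(ss: float, df_num: int, mse: float) -> float:
    """F statistic ``(SS / df_num) / MSE`` from a model comparison."""
    if df_num < 1:
        raise ValueError("numerator df must be >= 1")
    if mse <= 0:
        raise ValueError("MSE must be positive")
    return (ss / df_num) / mse


def ci_from_se(
    b: float, se: float, df_den: int, level: float = 0.95
) -> tuple[float, float]:
    """t-based confidence interval ``b +/- t((1+level)/2, df_den) * se``."""
    if se < 0:
        raise ValueError("SE must be non-negative")
    t = scipy.stats.t.ppf((1 + level) / 2, df_den)
    return b - t * se, b + t * se


def fit_level2(
    coefs,
    moderators: pd.DataFrame | None = None,
    term_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Across-participant OLS of a level-1 coefficient on centered moderators.

    ``moderators`` (participant x moderator, or None for an intercept-only
    model) are grand-mean centered here across the included participants.
    Returns one row per term with columns ``term, b, se, ci_lo, ci_hi, ss,
    mse, df_num, df_den, f, p, eta_p2``.  Per-term SS is
    ``SSE(term deleted) - SSE(full)``; the intercept's reduced model is the
    through-the-origin regression on the moderators alone.
    """
    y = np.asarray(coefs, dtype=float)
    n = y.size
    if moderators is None or (hasattr(moderators, "shape") and moderators.shape[1] == 0):
        M = np.empty((n, 0))
        names = []
    else:
        M = np.asarray(moderators, dtype=float)
        names = list(moderators.columns) if isinstance(moderators, pd.DataFrame) else [
            f"x{i}" for i in range(M.shape[1])
        ]
        M = M - M.mean(axis=0)
    if term_names is not None:
        names = list(term_names)
    p = 1 + M.shape[1]
    if n <= max(5, p):
        raise ValueError(f"too few participants (N={n}) for the level-2 model")
    X = np.column_stack([np.ones(n), M])
    coef, sse_full = _ols(y, X)
    df_den = n - p
    mse = sse_full / df_den
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(mse * np.diag(xtx_inv))

    rows = []
    all_terms = ["Intercept"] + names
    for j, term in enumerate(all_terms):
        X_red = np.delete(X, j, axis=1)
        if X_red.shape[1] == 0:
            sse_red = float(y @ y)
        else:
            _, sse_red = _ols(y, X_red)
        ss = max(sse_red - sse_full, 0.0)
        if mse > 0:
            f = f_from_ss(ss, 1, mse)
            pval = float(scipy.stats.f.sf(f, 1, df_den))
        else:
            # degenerate noise-free fit: coefficients identical across
            # participants, so the error variance vanishes
            f = np.inf if ss > 0 else 0.0
            pval = 0.0 if ss > 0 else 1.0
        lo, hi = ci_from_se(coef[j], se[j], df_den)
        rows.append(
            {
                "term": term,
                "b": coef[j],
                "se": se[j],
                "ci_lo": lo,
                "ci_hi": hi,
                "ss": ss,
                "mse": mse,
                "df_num": 1,
                "df_den": df_den,
                "f": f,
                "p": pval,
                "eta_p2": eta_p2(ss, df_den, mse) if mse > 0 else float(ss > 0),
            }
        )
    return pd.DataFrame(rows)


def fdr_adjust(pvals: pd.Series, a_priori: str | None = "Oz") -> pd.Series:
    """Benjamini-Hochberg adjustment across exploratory electrodes.

    ``pvals`` is indexed by electrode.  The a-priori channel is excluded from
    the family and carries its unadjusted p in the output.
    """
    p = pvals.astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = p.copy()
    family = p.index[p.index != a_priori] if a_priori is not None else p.index
    if len(family):
        _, adj, _, _ = multipletests(p.loc[family].to_numpy(), method="fdr_bh")
        out.loc[family] = adj
    return out


@dataclass
class BootstrapCorr:
    r: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int
    n_boot: int


def bootstrap_corr(x, y, n_boot: int = 2000, seed: int | None = None) -> BootstrapCorr:
    """Pearson r with a seeded percentile-bootstrap 95% CI.

    The two-tailed p comes from the t transform ``r*sqrt((n-2)/(1-r^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    rb = np.where(denom > 0, (xc * yc).sum(axis=1) / np.maximum(denom, 1e-300), np.nan)
    lo, hi = np.nanpercentile(rb, [2.5, 97.5])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * scipy.stats.t.sf(abs(t), n - 2))
    return BootstrapCorr(r=r, ci_lo=float(lo), ci_hi=float(hi), p=p, n=n, n_boot=n_boot)


class TwoStageMLM:
    """Two-stage multilevel model over a long (participant, electrode, block) table.

    Parameters
    ----------
    data
        Long DataFrame with one row per participant x electrode x block,
        holding the response, centered brightness codes, optionally the PSD
        predictor, and the participant-level moderator columns (repeated
        across rows).
    response
        Response column (``psd_db`` for the stimulation-response analysis,
        ``unpleasantness`` for the moderation analysis).
    include_psd
        Name of the PSD predictor column, or None to fit brightness only.
    moderators
        Participant-level moderator columns for the level-2 models (empty for
        intercept-only level-2 models).
    psd_centering
        ``"within"`` (default) centers the PSD predictor at each
        participant's own mean so the level-1 intercept is that participant's
        mean response; ``"grand"`` centers at the grand mean; ``"none"``
        leaves it raw.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        include_psd: str | None = None,
        moderators: tuple[str, ...] = (),
        participant: str = "participant",
        electrode: str | None = "electrode",
        brightness: str = "brightness",
        psd_centering: str = "within",
        a_priori_channel: str = "Oz",
    ) -> None:
        if psd_centering not in ("within", "grand", "none"):
            raise ValueError("psd_centering must be 'within', 'grand' or 'none'")
        self.data = data
        self.response = response
        self.include_psd = include_psd
        self.moderators = tuple(moderators)
        self.participant = participant
        self.electrode = electrode
        self.brightness = brightness
        self.psd_centering = psd_centering
        self.a_priori_channel = a_priori_channel

    @classmethod
    def from_tables(
        cls,
        psd_table: pd.DataFrame,
        participants: pd.DataFrame | None = None,
        ratings: pd.DataFrame | None = None,
        moderators: tuple[str, ...] = (),
        **kwargs,
    ) -> "TwoStageMLM":
        """Assemble the long table from pipeline outputs.

        ``psd_table`` is the long PSD table (participant, electrode,
        brightness, psd_db).  If ``ratings`` (participant, brightness,
        unpleasantness) is given the model is the moderation analysis with
        the unpleasantness response and PSD predictor, merging in
        ``participants`` for the moderator columns; otherwise it is the
        stimulation-response analysis on psd_db.
        """
        if ratings is None:
            return cls(psd_table, response="psd_db", **kwargs)
        data = psd_table.merge(ratings, on=["participant", "brightness"], how="left")
        if participants is not None:
            cols = ["participant", *moderators]
            data = data.merge(participants[cols], on="participant", how="left")
        return cls(
            data,
            response="unpleasantness",
            include_psd="psd_db",
            moderators=moderators,
            **kwargs,
        )

    # -- fitting ---------------------------------------------------------

    def _fit_level1_all(self) -> tuple[pd.DataFrame, list[str]]:
        rows, log = [], []
        elec_col = self.electrode
        df = self.data
        if elec_col is None or elec_col not in df.columns:
            df = df.assign(_electrode="__all__")
            elec_col = "_electrode"
        grand_psd = df[self.include_psd].mean() if self.include_psd else 0.0
        for (elec, pid), grp in df.groupby([elec_col, self.participant], sort=True):
            y = grp[self.response].to_numpy(dtype=float)
            x1 = grp[self.brightness].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(x1)
            psd = None
            if self.include_psd:
                psd = grp[self.include_psd].to_numpy(dtype=float)
                ok &= np.isfinite(psd)
            n_par = 3 if self.include_psd else 2
            if ok.sum() < n_par:
                log.append(f"{pid}/{elec}: only {int(ok.sum())} usable blocks; excluded")
                continue
            y, x1 = y[ok], x1[ok]
            if psd is not None:
                psd = psd[ok]
                if self.psd_centering == "within":
                    psd = psd - psd.mean()
                elif self.psd_centering == "grand":
                    psd = psd - grand_psd
            try:
                fit = fit_level1(y, x1, psd, participant=pid, electrode=elec)
            except np.linalg.LinAlgError:
                log.append(f"{pid}/{elec}: rank-deficient level-1 design; excluded")
                continue
            rows.append(
                {
                    "participant": pid,
                    "electrode": elec,
                    "b0": fit.b0,
                    "b1": fit.b1,
                    "b2": fit.b2,
                    "residual_df": fit.residual_df,
                }
            )
        return pd.DataFrame(rows), log

    def fit(self) -> "TwoStageResults":
        level1, log = self._fit_level1_all()
        if level1.empty:
            raise ValueError("no participant yielded a usable level-1 fit")
        mods = list(self.moderators)
        coef_models = [("Intercept", "b0"), ("Brightness", "b1")]
        if self.include_psd:
            coef_models.append(("PSD", "b2"))

        part_mods = None
        if mods:
            part_mods = (
                self.data[[self.participant, *mods]]
                .drop_duplicates(self.participant)
                .set_index(self.participant)
            )

        out = []
        for elec, grp in level1.groupby("electrode", sort=True):
            grp = grp.set_index("participant")
            if part_mods is not None:
                merged = grp.join(part_mods, how="inner").dropna(
                    subset=[c for _, c in coef_models] + mods
                )
            else:
                merged = grp.dropna(subset=[c for _, c in coef_models])
            for model_name, col in coef_models:
                res = fit_level2(
                    merged[col].to_numpy(dtype=float),
                    merged[mods] if mods else None,
                )
                res.insert(0, "model", model_name)
                res.insert(0, "electrode", elec)
                out.append(res)
        level2 = pd.concat(out, ignore_index=True)

        # FDR per (model, term) family across exploratory electrodes.
        level2["p_fdr"] = np.nan
        for (_, _), idx in level2.groupby(["model", "term"], sort=False).groups.items():
            sub = level2.loc[idx].set_index("electrode")["p"]
            adj = fdr_adjust(sub, a_priori=self.a_priori_channel)
            level2.loc[idx, "p_fdr"] = adj.to_numpy()

        results = TwoStageResults(model=self, level1=level1, level2=level2, log=log)
        results._check_identities()
        return results


class TwoStageResults:
    """Fitted two-stage model: level-1 coefficients and level-2 inference."""

    def __init__(
        self,
        model: TwoStageMLM,
        level1: pd.DataFrame,
        level2: pd.DataFrame,
        log: list[str],
    ) -> None:
        self.model = model
        self.level1 = level1
        self.level2 = level2
        self.log = log

    def _check_identities(self, rtol: float = 1e-8) -> None:
        """Internal consistency of every emitted row (F, eta_p2, CI)."""
        t2 = self.level2[self.level2["mse"] > 0]
        if t2.empty:
            return
        f = t2["ss"] / (t2["df_num"] * t2["mse"])
        if not np.allclose(f, t2["f"], rtol=rtol):
            raise AssertionError("F != SS/(df_num*MSE) in level-2 table")
        eta = t2["ss"] / (t2["ss"] + t2["df_den"] * t2["mse"])
        if not np.allclose(eta, t2["eta_p2"], rtol=rtol):
            raise AssertionError("eta_p2 identity violated in level-2 table")
        tq = scipy.stats.t.ppf(0.975, t2["df_den"])
        if not (
            np.allclose(t2["b"] - tq * t2["se"], t2["ci_lo"], rtol=rtol, atol=1e-12)
            and np.allclose(t2["b"] + tq * t2["se"], t2["ci_hi"], rtol=rtol, atol=1e-12)
        ):
            raise AssertionError("CI does not reconstruct from (b, se, df_den)")

    def electrode_table(self, electrode: str = "Oz") -> pd.DataFrame:
        sel = self.level2[self.level2["electrode"] == electrode]
        if sel.empty:
            raise KeyError(f"electrode {electrode!r} not in results")
        cols = [
            "model", "term", "b", "ci_lo", "ci_hi", "se",
            "ss", "mse", "f", "p", "p_fdr", "eta_p2",
        ]
        return sel[cols].reset_index(drop=True)

    def coef(self, electrode: str, model: str, term: str) -> pd.Series:
        sel = self.level2[
            (self.level2["electrode"] == electrode)
            & (self.level2["model"] == model)
            & (self.level2["term"] == term)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique row for ({electrode}, {model}, {term})")
        return sel.iloc[0]

    def summary(self, electrode: str = "Oz") -> str:
        """Table-style text summary for one electrode."""
        tab = self.electrode_table(electrode).copy()
        n = int(self.level1[self.level1["electrode"].isin([electrode, "__all__"])].shape[0])
        lines = [
            "Two-stage multilevel model results",
            f"Electrode: {electrode}   participants (level-2 N): {n}",
            f"Response: {self.model.response}   "
            f"moderators: {', '.join(self.model.moderators) or 'none'}",
            "",
            tab.to_string(
                index=False,
                float_format=lambda v: f"{v: .4g}",
            ),
        ]
        if self.log:
            lines += ["", f"{len(self.log)} level-1 exclusions (see .log)"]
        return "\n".join(lines)
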