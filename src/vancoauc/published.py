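"""Published benchmark constants of the source study.

The final population model coefficients live in
:data:`vancoauc.popmodel.PUBLISHED_MODEL`; this module carries the
published testing-set comparison table for the four AUC24 predictors,
used as the reference arithmetic for relative-improvement summaries.
"""

from __future__ import annotations

__all__ = ["PUBLISHED_COMPARISON", "mape_reduction"]

#: testing-set metrics of the four exposure predictors as published
#: (MAE mg*h/L, MSE (mg*h/L)^2, RMSE mg*h/L, MAPE %, R^2, F30 %)
PUBLISHED_COMPARISON: dict[str, dict[str, float]] = {
    "ppk": {"MAE": 308.91, "MSE": 169162.0, "RMSE": 308.91,
            "MAPE": 68.17, "R2": 0.64, "F30": 34.6},
    "bayesian": {"MAE": 84.91, "MSE": 15177.0, "RMSE": 84.94,
                 "MAPE": 13.37, "R2": 0.968, "F30": 94.2},
    "ml": {"MAE": 231.99, "MSE": 170093.0, "RMSE": 231.99,
           "MAPE": 34.17, "R2": 0.559, "F30": 61.5},
    "hybrid": {"MAE": 179.32, "MSE": 111204.0, "RMSE": 179.32,
               "MAPE": 28.52, "R2": 0.703, "F30": 76.9},
}


def mape_reduction(method: str, reference: str,
                   table: dict[str, dict[str, float]] | None = None) -> float:
    """Relative MAPE improvement of ``method`` over ``reference`` in percent.

    100 * (MAPE_ref - MAPE_method) / MAPE_ref — e.g. the hybrid model's
    improvement over the purely mechanistic predictor.
    """
    table = table if table is not None else PUBLISHED_COMPARISON
    ref = table[reference]["MAPE"]
    return 100.0 * (ref - table[method]["MAPE"]) / ref
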