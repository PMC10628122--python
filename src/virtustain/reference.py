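"""Published per-donor DFI error values for virtually stained human sperm.

These are the per-donor MAE and MAPE values reported for GAN-based virtual
staining of the six-donor human sperm dataset (Donor 1 held out for testing,
Donors 2-6 used for training), for three model variants: pix2pix trained on
noisy fluorescence targets, pix2pix trained on denoised targets, and the
spectrally-normalized variant (pix2pix++) trained on denoised targets.  They
serve as worked-example inputs for the report-aggregation utilities: feeding
a column into :func:`virtustain.quantify.aggregate_report` reproduces the
published Mean / S.D. rows and the training-set summary (0.0204 +- 0.0033 for
the denoised pix2pix MAE over Donors 2-6).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_errors", "TEST_DONORS", "ORIGINAL_STUDY_MEAN_MAE"]

TEST_DONORS = ("Donor 1",)

#: Mean MAE reported by the earlier regression-CNN study on the same dataset.
ORIGINAL_STUDY_MEAN_MAE = 0.023

_DONORS = ["Donor 1", "Donor 2", "Donor 3", "Donor 4", "Donor 5", "Donor 6"]

_VALUES = {
    ("pix2pix_noisy", "mae"): [0.0235, 0.0243, 0.0229, 0.0211, 0.0217, 0.0229],
    ("pix2pix_noisy", "mape"): [0.2403, 0.3868, 0.1461, 0.1946, 0.3012, 0.2417],
    ("pix2pix_denoised", "mae"): [0.0220, 0.0179, 0.0257, 0.0191, 0.0179, 0.0214],
    ("pix2pix_denoised", "mape"): [0.2250, 0.2857, 0.1643, 0.1761, 0.2482, 0.2250],
    ("pix2pixpp_denoised", "mae"): [0.0198, 0.0164, 0.0230, 0.0215, 0.0182, 0.0206],
    ("pix2pixpp_denoised", "mape"): [0.2025, 0.2611, 0.1467, 0.1981, 0.2521, 0.2165],
}


def published_errors(model: str | None = None) -> pd.DataFrame:
    """Per-donor published error values.

    Returns a tidy frame with columns ``donor``, ``model``, ``mae``, ``mape``;
    pass ``model`` (``pix2pix_noisy``, ``pix2pix_denoised`` or
    ``pix2pixpp_denoised``) to select one variant.
    """
    frames = []
    for mdl in ("pix2pix_noisy", "pix2pix_denoised", "pix2pixpp_denoised"):
        frames.append(
            pd.DataFrame(
                dict(
                    donor=_DONORS,
                    model=mdl,
                    mae=_VALUES[(mdl, "mae")],
                    mape=_VALUES[(mdl, "mape")],
                )
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if model is not None:
        if model not in df["model"].unique():
            raise ValueError(f"unknown model {model!r}")
        df = df[df["model"] == model].reset_index(drop=True)
    return df
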