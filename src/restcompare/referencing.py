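"""Reference transforms: average reference (AR) and standardization to an
infinity reference (REST).

AR subtracts the instantaneous mean over channels — adequate only insofar as
the electrode average approximates a neutral point.  REST instead exploits
the forward model: any scalp topography in the span of an equivalent-source
lead field ``G`` has a unique reference-free (infinity) representation.  With
``G_ar`` the channel-mean-centred gain, the average-referenced data ``V_ar``
are mapped back through the sources,

    V_inf = G . pinv(G_ar) . V_ar,

which restores the common-mode component AR removed, up to the model's span.
"""

from __future__ import annotations

import logging

import numpy as np

from .headmodel import LeadField
from .recording import (
    EEGRecording,
    REF_AVERAGE,
    REF_INFINITY,
    common_reference_label,
    is_common_reference,
)

logger = logging.getLogger(__name__)


def to_common_reference(rec: EEGRecording, label: str) -> EEGRecording:
    """Re-express against a single electrode (its trace becomes zero)."""
    idx = rec.channel_index([label])[0]
    data = rec.data - rec.data[idx]
    from .recording import common_reference

    return rec.copy_with(data=data, reference=common_reference(label))


def to_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels.

    If the recording is referenced at a common electrode that is absent from
    the channel set, a zero trace for it is restored first so the average is
    taken over the full electrode set.
    """
    data, labels = rec.data, list(rec.labels)
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    if is_common_reference(rec.reference):
        ref_label = common_reference_label(rec.reference)
        if ref_label not in labels:
            data = np.vstack([data, np.zeros((1, rec.n_samples))])
            labels = labels + [ref_label]
    data = data - data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, labels=labels, reference=REF_AVERAGE)


def rest_transform(
    rec_ar: EEGRecording, lf: LeadField, svd_tol: float = 1e-4
) -> EEGRecording:
    """Standardize average-referenced data to the infinity reference.

    Parameters
    ----------
    rec_ar
        Average-referenced recording; channel order must match ``lf.labels``.
    lf
        Infinity-referenced equivalent-source lead field.
    svd_tol
        Relative singular-value cutoff for the pseudoinverse of the
        channel-mean-centred gain (which is always rank-deficient by at
        least one, since centring removes the common mode).
    """
    if rec_ar.reference != REF_AVERAGE:
        raise ValueError(
            f"rest_transform expects an average-referenced input, got {rec_ar.reference!r}"
        )
    if tuple(rec_ar.labels) != tuple(lf.labels):
        raise ValueError("channel order of recording and lead field disagree")
    G = lf.gain
    G_ar = G - G.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(G_ar, full_matrices=False)
    keep = s > svd_tol * s[0]
    rank = int(keep.sum())
    if rank < min(G_ar.shape) - 1:
        logger.warning(
            "equivalent-source gain is rank deficient beyond the expected "
            "common-mode: effective rank %d of %d", rank, min(G_ar.shape)
        )
    pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
    data = G @ (pinv @ rec_ar.data)
    return rec_ar.copy_with(data=data, reference=REF_INFINITY)
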