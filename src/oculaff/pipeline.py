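"""End-to-end convenience: raw recording -> events -> 28-feature row."""

from __future__ import annotations

import pandas as pd

from .events import IVTEventDetector
from .features import GazeFeatureExtractor
from .preprocess import preprocess
from .recordings import RawRecording, ScreenGeometry


def process_recording(rec: RawRecording, geom: ScreenGeometry | None = None,
                      detector: IVTEventDetector | None = None,
                      extractor: GazeFeatureExtractor | None = None) -> dict[str, float]:
    """Run the full extraction pipeline on one recording."""
    detector = detector or IVTEventDetector()
    extractor = extractor or GazeFeatureExtractor()
    series = preprocess(rec, geom,
                        confidence_threshold=detector.blink_confidence_threshold)
    events = detector.detect(series, rec)
    from .features import extract_features
    return extract_features(events, rec, extractor.confidence_threshold,
                            extractor.excess_kurtosis)


def feature_table(recordings, geom: ScreenGeometry | None = None,
                  detector: IVTEventDetector | None = None,
                  extractor: GazeFeatureExtractor | None = None) -> pd.DataFrame:
    """Feature rows for many recordings, indexed by (participant, video)."""
    rows, index = [], []
    for rec in recordings:
        rows.append(process_recording(rec, geom, detector, extractor))
        index.append((rec.participant_id, rec.video_id))
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["participant_id", "video_id"]))
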