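"""Exception hierarchy for vbtcam."""


class VbtCamError(Exception):
    """Base class for all vbtcam errors."""


class GeometryError(VbtCamError):
    """Measured machine geometry is internally impossible (triangle inequality)."""


class MeasurementInconsistencyError(GeometryError):
    """The redundant sixth tape-measured distance disagrees beyond tolerance."""


class CalibrationError(VbtCamError):
    """Homography/pose estimation failed (degenerate or insufficient data)."""


class DegenerateViewError(CalibrationError):
    """Focal self-calibration impossible (fronto-parallel view)."""


class PointBehindCameraError(VbtCamError):
    """A scene point has non-positive depth in the camera frame."""


class DetectionError(VbtCamError):
    """Marker or reference-tape detection failed on a frame."""


class TrackingError(VbtCamError):
    """Barbell track is unusable (e.g. no detections at all)."""


class InputError(VbtCamError):
    """Unreadable, empty, or inconsistent input data."""
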