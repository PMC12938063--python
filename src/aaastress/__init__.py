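"""aaastress: image-based abdominal aortic aneurysm wall-stress pipeline.

Segmentation of the outer aortic wall, NURBS contour refinement, surface
lofting, inverse membrane (NEMA) wall-stress estimation, and the
segmentation / biomechanical evaluation metrics around them.
"""

__version__ = "0.1.0"

from . import biomech, geometry, nema, nurbs, phantom, segmetrics

__all__ = [
    "biomech", "geometry", "io", "nema", "nurbs", "phantom", "pipeline",
    "segmentation", "segmetrics", "__version__",
]


def __getattr__(name):
    # io / pipeline / segmentation are imported lazily: they pull in file
    # and CLI dependencies not needed for the numerical core
    if name in ("io", "pipeline", "segmentation", "nn", "cli"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
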