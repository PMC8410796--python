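"""dermbalance: class-imbalance-aware training and evaluation for binary
dermoscopic lesion classification.

Core pieces:

* :mod:`dermbalance.losses` — the class-wise loss family, including the
  balanced custom loss ``a*(pmse+nmse)**2 + b*(pmse-nmse)**2``;
* :mod:`dermbalance.sampling` — fixed-ratio mini-batch composition;
* :mod:`dermbalance.augment` — preprocessing and real-time affine
  augmentation;
* :mod:`dermbalance.models` — the reformed fully-connected head and a tiny
  CPU-trainable convolutional backbone;
* :mod:`dermbalance.training` — ORI/BON/BLF scenario training with a
  triangular2 cyclical learning rate;
* :mod:`dermbalance.evaluation` — SEN/SPE/ROC/AUC, threshold sweeps,
  balanced operating points and model-versus-reader comparison;
* :mod:`dermbalance.synth` — seeded synthetic lesion-image and score
  generators for offline experiments.
"""

from importlib.resources import files as _files

import pandas as _pd

from .losses import (
    LabeledBatch,
    LossParams,
    ConfusionCounts,
    ClasswiseLoss,
    mse,
    pmse,
    nmse,
    clf,
    clf_from_confusion,
    binary_cross_entropy,
    focal_loss,
)
from .sampling import SamplingPlan, EpochSchedule, make_epoch, naive_epoch
from .augment import AugmentConfig, PreprocessSpec, preprocess, augment
from .models import HeadConfig, BackboneContract, build_head, build_tiny_backbone, Classifier
from .training import CLRConfig, OptimizerConfig, ScenarioConfig, TrainingHistory, clr_at, train
from .evaluation import (
    ROCCurve,
    OperatingPoint,
    ReaderPoint,
    sensitivity,
    specificity,
    accuracy,
    confusion_at_threshold,
    roc_and_auc,
    threshold_sweep,
    balanced_threshold,
    readers_outperformed,
)
from .synth import SynthConfig, generate_arrays, generate_dataset, generate_scores

__version__ = "0.1.0"


def reader_groups() -> "_pd.DataFrame":
    """Packaged reader-study group operating points (AUC/SEN/SPE in %),
    as published for a 157-dermatologist benchmark; fixture input data
    for model-versus-reader demonstration reports."""
    path = _files("dermbalance.data").joinpath("reader_groups.csv")
    return _pd.read_csv(path)


def reader_points() -> list[ReaderPoint]:
    """The packaged reader groups as :class:`ReaderPoint` objects."""
    frame = reader_groups()
    return [
        ReaderPoint(sen=row.sen / 100.0, spe=row.spe / 100.0, group_label=row.group)
        for row in frame.itertuples()
    ]
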