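"""hilofuse: high/low-frequency multimodal feature fusion for MDD-vs-HC
classification.

The package implements a three-branch multimodal classifier for major
depressive disorder: a convolutional meta-high-frequency encoder (MHFE) and a
transformer meta-low-frequency encoder (MLFE) shared across structural MRI
and DTI fractional-anisotropy volumes, an MLP on the fMRI functional-
connectivity matrix, pairwise cross-fusion of the four frequency features
into six logits, and threshold majority voting over the seven resulting
probabilities.  A synthetic-cohort generator with planted frequency-specific
class effects makes every stage testable without clinical data.
"""

from .cohort_sim import (
    CohortManifest,
    SimParams,
    generate_cohort,
    simulate_timeseries,
    write_cohort,
)
from .encoders import (
    EncoderConfig,
    FCMLP,
    MHFE,
    MLFE,
    fc_mlp_forward,
    mhfe_forward,
    mlfe_forward,
)
from .fusion_model import (
    FeatureBundle,
    FusionModel,
    VoteConfig,
    cross_fuse,
    forward_subject,
    load_checkpoint,
    majority_vote,
    save_checkpoint,
    sigmoid,
)
from .metrics import (
    AmbiguousRowError,
    ConfusionMatrix,
    InconsistentRowError,
    MetricSet,
    audit_table,
    confusion_metrics,
    metric_mean_sd,
    roc_auc,
    solve_confusion,
)
from .train_eval import (
    CVSummary,
    TrainConfig,
    TrainingDivergedError,
    compute_loss,
    cross_validate,
    evaluate,
    run_ablation,
    split_train_test,
    train,
    voters_for_branches,
    voters_for_modalities,
)
from .volume_io import (
    SubjectRecord,
    load_manifest,
    normalize_volume,
    pearson_fc,
    resample_nearest,
)

__version__ = "0.1.0"
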