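"""Iteratively delete the worst-error landmarks and watch the MAE fall.

Starting from the 20-landmark (45 degrees) constellation on a 2.4-turn
cochlea with voxel-quantized targets, delete batches of the highest-error
landmarks, re-register after each batch, and protect the apical landmark
(it anchors the cochlea's height, so it must survive even when its error
ranks worst).
"""

from cochreg import (
    PhantomSpec,
    PlacementScheme,
    PruningPlan,
    make_phantom,
    mean_params,
    prune,
)
from cochreg.io import report_table

phantom = make_phantom(
    PhantomSpec(
        params=mean_params(turns=2.4),
        scheme=PlacementScheme(45),
        noise="quantize",
        seed=7,
    )
)
apex_label = len(phantom.model_landmarks)  # the terminal (apical) landmark
plan = PruningPlan(
    batch_sizes=(3, 2, 2, 1, 1, 1, 1),
    min_landmarks=5,
    protected=frozenset({apex_label}),
)
report = prune(phantom.model_landmarks, phantom.target_landmarks, plan)

print(report_table(report))
print()
for name, value in report.reductions.items():
    print(f"MAE reduction {name}: {value:.2f}%")
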