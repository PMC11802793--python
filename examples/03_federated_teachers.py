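"""Stage 1: train one task-specific teacher with simulated FedAvg.

Each federated round broadcasts the server weights, trains locally on every
client that owns the task's labels, and averages the returned weights
(weighted by labeled sample count).  The held-out client is never read.
"""

import numpy as np

from fedct.core import TASK_LANDMARKS
from fedct.distill import teacher_predict
from fedct.evaluation import point_error_mm
from fedct.federation import run_stage1
from fedct.models import TeacherConfig, TeacherNet
from fedct.phantom import PhantomConfig, default_annotators, make_federation, tiny_spec

spec = tiny_spec()
shards, plan = make_federation(spec, PhantomConfig(), default_annotators(spec),
                               seed=1, rounds=5, epochs=2)

config = TeacherConfig(task="MS", base_filters=8, depth=2)
state, log = run_stage1(plan, shards, "MS", config, seed=11)

print("per-round mean training loss:")
for r in log["rounds"]:
    losses = [np.mean(tr) for tr in r["loss"].values()]
    print(f"  round {r['round']}: {np.mean(losses):.3f} (client weights {r['weights']})")

net = TeacherNet(config, seed=0)
net.load_state(state)
held_out = next(s for s in shards if s.client_id == plan.held_out_clients["MS"][0])
errors = []
for s in held_out.samples:
    pred, degenerate, _ = teacher_predict(net, s)
    _, mean_err, _ = point_error_mm(pred, s.points_true.subset(TASK_LANDMARKS["MS"]))
    errors.append(mean_err)
print(f"\nheld-out client {held_out.client_id}: "
      f"mean MS landmark error {np.mean(errors):.2f} mm over {len(errors)} samples")
# The error is measured against the generator's ground truth, which no
# training stage ever saw.
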