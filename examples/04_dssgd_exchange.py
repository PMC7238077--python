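"""The DSSGD parameter exchange, step by step, on a toy vector.

Shows what one worker shares after a local epoch: updates below the
threshold tau are withheld, the rest are clamped to [-gamma, +gamma] and
subsampled to the upload cap floor(theta_u * len(p)); the server adds them
to the global vector and bumps per-parameter counters, and downloads return
the most-updated parameters (ties toward the lowest index).
"""

import numpy as np

from phideid.training import (
    ServerState,
    SparseUpdate,
    WorkerConfig,
    select_updates,
    server_download,
    server_upload,
)

cfg = WorkerConfig(theta_d=0.4, theta_u=0.5, gamma=10.0, tau=1e-4, eta=0.9, seed=0)

delta = np.array([0.00005, 15.0, -0.5, 0.0, 2.0, -0.00002, 0.3, -12.0, 0.001, 0.0])
print("local updates after one epoch:", delta)

update = select_updates(delta, cfg)
print(f"\nshared after tau filter + gamma clamp + cap floor(0.5*10)={5}:")
for j, v in zip(update.indices, update.values):
    note = "  (clamped)" if abs(delta[j]) > cfg.gamma else ""
    print(f"  p[{j}] += {v}{note}")

state = ServerState(p_glo=np.zeros(10), update_counts=np.zeros(10, dtype=np.int64))
server_upload(state, update)
server_upload(state, SparseUpdate(np.array([1, 4]), np.array([0.1, 0.1])))
print("\nserver counters:", state.update_counts)

download = server_download(state, cfg.theta_d)
print(f"download (top floor(0.4*10)={4} by count, ties to lowest index):",
      download.indices, "->", download.values)
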