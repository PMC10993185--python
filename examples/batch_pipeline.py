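"""Batch processing with staged intermediate files, as the CLI `run` does.

Simulates three participants into a temp directory and runs the staged
pipeline over them; each stage writes its artifact (cleaned CSV,
transition CSV, edge list, GraphML, metrics JSON) before the next starts.
"""

import tempfile
from pathlib import Path

from gazenet import (
    PipelineConfig, SessionConfig, classroom_model, classroom_scene,
    run_pipeline, synthesize_session,
)

root = Path(tempfile.mkdtemp(prefix="gazenet_demo_"))
indir = root / "raw"
indir.mkdir()
scene = classroom_scene()
scene.to_yaml(root / "scene.yaml")

for i in range(3):
    cfg = SessionConfig(scene=scene, model=classroom_model(),
                        duration_s=60, seed=200 + i, participant_id=f"p{i}")
    raw, _ = synthesize_session(cfg)
    raw.to_csv(indir / f"p{i}.csv", index=False)

config = PipelineConfig(
    input_dir=indir, output_dir=root / "out", scene_file=root / "scene.yaml",
    groups={"front": ["teacher", "board"]},
)
summary = run_pipeline(config)
print(summary[["participant", "n_raw", "n_clean", "n_dropped",
               "n_transitions", "n_edges", "status"]].to_string(index=False))
print(f"\nartifacts in {root / 'out'}:")
for p in sorted((root / "out").iterdir()):
    print(f"  {p.name}")
# Row counts shrink monotonically through the stages (raw >= clean >=
# transitions >= edges): each stage aggregates, never expands.
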