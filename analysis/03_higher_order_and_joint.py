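"""Stage 3 — higher-order motivations, the joint domain, and refined subsets.

Runs IITA on autonomous (intrinsic + identified) and controlled (external +
introjected) motivation, on all 19 motivations jointly (exploratory, small
N = 180), and on the three refined overlapping subsets A, B, C delineated
from the joint solution.  The higher-order scales come out as chains —
interweaving intermediate with polar regulations — while the joint solution
is branched.
"""

import json
from pathlib import Path

from motispace import dimensionality_report, load_fixture, select_solution, states_from_relation
from motispace.io import export_relation, write_state_space

OUT = Path(__file__).resolve().parent.parent / "results" / "joint"
OUT.mkdir(parents=True, exist_ok=True)

summary = {}
for name in ("autonomous", "controlled", "all", "subset_A", "subset_B", "subset_C"):
    data = load_fixture(name)
    result = select_solution(data)
    rep = dimensionality_report(result.solution)
    export_relation(result.solution, "edges", OUT / f"{name}_relation.tsv")
    export_relation(result.solution, "dot", OUT / f"{name}_relation.dot")
    if name in ("autonomous", "controlled"):
        write_state_space(states_from_relation(result.solution), OUT / f"{name}_space.txt")
    summary[name] = {
        "N": data.N,
        "m": data.m,
        "selected_L": result.record.L,
        "gamma": result.record.gamma,
        "diff": result.record.diff,
        "width": rep.width,
        "is_chain": rep.is_chain,
        "blocks": [list(b) for b in rep.blocks.blocks],
    }
    print(
        f"{name:10s} N={data.N:4d} m={data.m:2d}  L={result.record.L:3d} "
        f"gamma={result.record.gamma:.4f} diff={result.record.diff:8.3f}  "
        f"width={rep.width}  chain={rep.is_chain}"
    )

(OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print(
    "\nAutonomous and controlled motivation are chains (higher-order gradations);\n"
    "subsets B and C are chains, subset A and the joint solution are branched "
    "(width 2).  Wrote " + str(OUT)
)
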