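"""Shared builders for prep/pipeline tests."""

import pandas as pd

from mfisplit.frailty import INDICATORS


def make_records(dest_counts: dict[str, int], specialty: str = "general") -> pd.DataFrame:
    """Minimal complete cohort frame with prescribed destination counts."""
    rows = []
    i = 0
    for dest, n in dest_counts.items():
        for _ in range(n):
            row = {"record_id": f"R{i:06d}", "specialty": specialty}
            row.update({k: (i + j) % 2 for j, k in enumerate(INDICATORS)})
            row.update(
                age=40 + i % 50, sex="male" if i % 2 else "female",
                wrvu=10.0 + i, asa_class=1 + i % 5, destination=dest,
            )
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)
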