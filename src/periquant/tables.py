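"""Toy differential-expression, ligand-receptor and receiver-profile tables.

These generators emulate the tabular inputs of the communication analysis
without any download: a bulk-RNA-seq-style DE table in which the
injury-responsive pro-algesic ligands (Il6, Lif, Clcf1, Ccl2, Ngf, Tnc, Spp1,
Mmp9) are strongly upregulated against a background of null genes; a small
curated ligand -> receptor-subunit database with family labels; and receptor
expression profiles for three sensory-neuron receiver populations
(neurofilament-positive neurons, nociceptors, C-low-threshold
mechanoreceptors), all of which express the gp130 co-receptor Il6st.

Everything is synthetic: values are plausible in scale but are not drawn from
any sequencing dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ligand_receptor import LRPair, ReceiverProfile, validate_de_table

__all__ = [
    "INJURY_LIGANDS",
    "toy_lr_database",
    "toy_de_table",
    "toy_receiver_profiles",
    "sender_expression",
    "lr_database_to_frame",
    "lr_database_from_frame",
]

INJURY_LIGANDS = ("Il6", "Lif", "Clcf1", "Ccl2", "Ngf", "Tnc", "Spp1", "Mmp9")


def toy_lr_database() -> tuple[LRPair, ...]:
    """A small multi-subunit-aware ligand/receptor database with family labels.

    gp130-family cytokines require the shared Il6st chain plus their private
    alpha receptors; decoy pairs whose receptors no receiver expresses are
    included so that matching is non-trivial.
    """
    return (
        LRPair("Il6", ("Il6ra", "Il6st"), "cytokine", "toy"),
        LRPair("Lif", ("Lifr", "Il6st"), "cytokine", "toy"),
        LRPair("Clcf1", ("Cntfr", "Lifr", "Il6st"), "cytokine", "toy"),
        LRPair("Ccl2", ("Ccr2",), "chemokine", "toy"),
        LRPair("Ngf", ("Ntrk1",), "growth factor", "toy"),
        LRPair("Ngf", ("Ngfr",), "growth factor", "toy"),
        LRPair("Tnc", ("Itgb1", "Itga9"), "ECM", "toy"),
        LRPair("Spp1", ("Itgav", "Itgb3"), "ECM", "toy"),
        LRPair("Spp1", ("Cd44",), "adhesion", "toy"),
        LRPair("Mmp9", ("Lrp1",), "ECM", "toy"),
        LRPair("Ncam1", ("Ncam1",), "adhesion", "toy"),
        # decoys: receptors absent from every toy receiver profile
        LRPair("Epo", ("Epor",), "other", "toy"),
        LRPair("Ins1", ("Insr",), "other", "toy"),
        LRPair("Gh", ("Ghr",), "other", "toy"),
    )


def toy_de_table(
    seed: int = 0,
    n_null: int = 40,
    n_down: int = 6,
    up_log2fc_range: tuple[float, float] = (3.5, 6.0),
) -> pd.DataFrame:
    """Injury (condition B) vs control (condition A) DE table for the sender.

    The pro-algesic ligands come out strongly upregulated (log2FC above the
    eightfold volcano cutoff, tiny adjusted p); null genes scatter around
    log2FC 0 with non-significant p; a few genes are significantly
    downregulated. Columns: gene, log2fc, padj, mean_a, mean_b.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in INJURY_LIGANDS:
        lfc = rng.uniform(*up_log2fc_range)
        base = rng.uniform(5.0, 50.0)
        rows.append((g, lfc, rng.uniform(1e-10, 1e-4), base, base * 2.0**lfc))
    for i in range(n_down):
        lfc = -rng.uniform(1.5, 4.0)
        base = rng.uniform(20.0, 200.0)
        rows.append((f"Down{i}", lfc, rng.uniform(1e-6, 0.01), base, base * 2.0**lfc))
    for i in range(n_null):
        lfc = rng.normal(0.0, 0.4)
        base = rng.uniform(1.0, 500.0)
        rows.append((f"Null{i}", lfc, rng.uniform(0.05, 1.0), base, base * 2.0**lfc))
    de = pd.DataFrame(rows, columns=["gene", "log2fc", "padj", "mean_a", "mean_b"])
    return validate_de_table(de)


def toy_receiver_profiles(seed: int = 0) -> dict[str, ReceiverProfile]:
    """Receptor expression for NF, nociceptor and cLTMR receiver populations.

    All three subtypes express Il6st and Itgb1; receptor alpha chains are
    distributed subtype-specifically (e.g. Ntrk1 and Ccr2 on nociceptors,
    Cntfr on NF neurons). Values are arbitrary positive expression units.
    """
    rng = np.random.default_rng(seed)
    base = {
        "NF": {
            "Il6st": 8.0, "Il6ra": 1.5, "Lifr": 3.0, "Cntfr": 6.0,
            "Ntrk1": 2.0, "Itgb1": 7.0, "Itga9": 2.5, "Cd44": 1.0,
            "Lrp1": 4.0, "Ncam1": 9.0,
        },
        "nociceptor": {
            "Il6st": 9.0, "Il6ra": 4.0, "Lifr": 2.0, "Cntfr": 3.0,
            "Ccr2": 3.5, "Ntrk1": 8.0, "Ngfr": 5.0, "Itgb1": 6.0,
            "Itga9": 1.5, "Itgav": 2.0, "Itgb3": 1.8, "Cd44": 2.5,
            "Lrp1": 3.0, "Ncam1": 6.0,
        },
        "cLTMR": {
            "Il6st": 7.0, "Lifr": 1.2, "Ngfr": 2.0, "Itgb1": 5.0,
            "Itga9": 1.0, "Cd44": 1.5, "Lrp1": 2.0, "Ncam1": 7.0,
        },
    }
    out = {}
    for label, expr in base.items():
        jitter = {g: max(v * rng.uniform(0.8, 1.2), 0.0) for g, v in expr.items()}
        out[label] = ReceiverProfile(label=label, expression=jitter)
    return out


def sender_expression(de: pd.DataFrame, condition: str = "post") -> dict[str, float]:
    """Sender expression vector from a DE table's condition means.

    ``'pre'`` uses mean_a (control), ``'post'`` uses mean_b (injured).
    """
    col = {"pre": "mean_a", "post": "mean_b"}.get(condition)
    if col is None:
        raise ValueError("condition must be 'pre' or 'post'")
    return dict(zip(de["gene"], de[col].astype(float)))


def lr_database_to_frame(db: tuple[LRPair, ...]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ligand": [p.ligand for p in db],
            "receptors": [";".join(p.receptors) for p in db],
            "family": [p.family for p in db],
            "source": [p.source for p in db],
        }
    )


def lr_database_from_frame(df: pd.DataFrame) -> tuple[LRPair, ...]:
    return tuple(
        LRPair(
            ligand=row["ligand"],
            receptors=tuple(row["receptors"].split(";")),
            family=row.get("family", "other"),
            source=row.get("source", ""),
        )
        for _, row in df.iterrows()
    )
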