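"""Synthetic single-cell BCR repertoires with known clonal and mutational truth.

The generator emulates the statistical structure the downstream analyses
assume: a power-law clone-size distribution with expanded and singleton
clones, germline-anchored paired heavy/light sequences accumulating point
substitutions over rounds of somatic hypermutation (SHM), and isotype
switching coupled to mutation load. No indels are simulated — the Hamming /
equal-length rules of the SHM analyses would drop indel cells anyway.

Maturation model
----------------
Every cell of a clone draws an independent maturation stage
``t ~ Uniform{0..max_shm_rounds}``. Its lineage parent is chosen uniformly
among previously generated clone members whose stage does not exceed ``t``
(the germline, stage 0, is always eligible), and ``t - t_parent`` SHM rounds
are applied on the connecting edge, each round substituting
``per_round_substitutions`` uniformly chosen positions. This yields branching
germline-rooted truth trees, expanded identical-sequence nodes (cells sampled
at the same stage), and — because stages are drawn independently of clone
size — per-cell SHM that is decoupled from clonal expansion.

Substitution targets are drawn uniformly from the 19 alternative residues by
default, or from a likelihood provider's per-position distribution
(``mutation_strategy="provider_guided"``) to emulate model-favoured mutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, N_AA
from .errors import ConfigError, DataError
from .io import hamming_shm, write_airr
from .likelihood import LikelihoodProvider
from .records import CellRecord, ChainRecord, Repertoire, v_family

_ISOTYPE_C_CALL = {"IgM": "IGHM", "IgG": "IGHG1", "IgA": "IGHA1"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic repertoire.

    Defaults describe a mid-sized immunized sample: ~1000 paired cells over a
    handful of germlines, variable regions of 110 aa with a CDR3 of 12 aa near
    the junction, up to 8 SHM rounds of 2 substitutions each, and moderate
    SHM-coupled class switching.
    """

    n_cells: int = 1000
    n_germlines: int = 8
    vdj_length: int = 110
    cdr3_span: tuple[int, int] = (95, 107)
    clone_size_alpha: float = 2.5
    max_shm_rounds: int = 8
    per_round_substitutions: int = 2
    switch_coupling: float = 0.3
    affinity_coupling: float = 0.2
    seed: int = 0
    mutation_strategy: str = "uniform"  # "uniform" | "provider_guided"

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_germlines <= 0 or self.vdj_length <= 0:
            raise ConfigError("n_cells, n_germlines and vdj_length must be positive")
        s, e = self.cdr3_span
        if not (0 <= s < e <= self.vdj_length):
            raise ConfigError(f"cdr3_span {self.cdr3_span} outside [0, {self.vdj_length})")
        if self.max_shm_rounds < 0 or self.per_round_substitutions <= 0:
            raise ConfigError("invalid SHM round parameters")
        if self.per_round_substitutions * self.max_shm_rounds >= self.vdj_length:
            raise ConfigError("mutation saturation: per_round_substitutions * max_shm_rounds >= vdj_length")
        if not (0.0 <= self.switch_coupling <= 1.0):
            raise ConfigError("switch_coupling must lie in [0, 1]")
        if self.clone_size_alpha <= 0:
            raise ConfigError("clone_size_alpha must be positive")
        if self.mutation_strategy not in ("uniform", "provider_guided"):
            raise ConfigError(f"unknown mutation_strategy {self.mutation_strategy!r}")


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    clone_id: str
    parent_cell_id: str | None  # None = direct child of the germline
    rounds: int  # total SHM rounds from germline to this cell (heavy chain)
    substitutions_heavy: list[tuple[int, str, str]]  # (position, from, to), germline->cell order
    substitutions_light: list[tuple[int, str, str]]
    switched: bool


@dataclass
class SimulatedRepertoire:
    """Cells plus per-cell truth; convertible to a plain :class:`Repertoire`."""

    cells: list[CellRecord]
    truth: dict[str, CellTruth]
    heavy_germlines: dict[str, str]  # v_call -> sequence
    light_germlines: dict[str, str]
    config: SimulationConfig

    def to_repertoire(self) -> Repertoire:
        assignment = {cid: t.clone_id for cid, t in self.truth.items()}
        return Repertoire(cells=list(self.cells), clone_assignment=assignment, filter_log={})

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """AIRR TSV plus a JSON truth sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        airr = out_dir / "repertoire.airr.tsv"
        truth = out_dir / "truth.json"
        write_airr(self.cells, airr, {cid: t.clone_id for cid, t in self.truth.items()})
        payload = {
            cid: {
                "clone_id": t.clone_id,
                "parent_cell_id": t.parent_cell_id,
                "rounds": t.rounds,
                "substitutions_heavy": t.substitutions_heavy,
                "substitutions_light": t.substitutions_light,
                "switched": t.switched,
            }
            for cid, t in self.truth.items()
        }
        truth.write_text(json.dumps(payload))
        return {"airr": airr, "truth": truth}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, size=length))


def _clone_sizes(rng: np.random.Generator, n_cells: int, alpha: float) -> list[int]:
    """Discrete power law P(s) ~ s^-alpha truncated at n_cells; trimmed to sum exactly."""
    support = np.arange(1, n_cells + 1)
    weights = support.astype(float) ** -alpha
    weights /= weights.sum()
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        s = int(rng.choice(support, p=weights))
        s = min(s, n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    rounds: int,
    per_round: int,
    strategy: str,
    provider: LikelihoodProvider | None,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply `rounds` SHM rounds; returns the new sequence and the event log."""
    seq = list(sequence)
    events: list[tuple[int, str, str]] = []
    for _ in range(rounds):
        positions = rng.choice(len(seq), size=per_round, replace=False)
        matrix = None
        if strategy == "provider_guided":
            matrix = provider.residue_probabilities("".join(seq))
        for pos in positions:
            current = seq[pos]
            if matrix is None:
                alternatives = [aa for aa in AMINO_ACIDS if aa != current]
                new = alternatives[int(rng.integers(0, N_AA - 1))]
            else:
                col = matrix.probs[pos].copy()
                col[AMINO_ACIDS.index(current)] = 0.0
                col /= col.sum()
                new = AMINO_ACIDS[int(rng.choice(N_AA, p=col))]
            events.append((int(pos), current, new))
            seq[pos] = new
    return "".join(seq), events


def simulate_repertoire(
    config: SimulationConfig,
    mutation_provider: LikelihoodProvider | None = None,
) -> SimulatedRepertoire:
    """Generate a paired-chain repertoire with full mutational truth.

    Deterministic given ``config.seed``. ``mutation_provider`` is required for
    (and only used by) the ``provider_guided`` strategy; its matrices are
    computed on the fly for each intermediate parent sequence.
    """
    if config.mutation_strategy == "provider_guided" and mutation_provider is None:
        raise ConfigError("provider_guided strategy requires a mutation_provider")
    rng = np.random.default_rng(config.seed)

    heavy_germlines = {
        f"IGHV{i + 1}": _random_sequence(rng, config.vdj_length)
        for i in range(config.n_germlines)
    }
    light_germlines = {
        f"IGKV{i + 1}": _random_sequence(rng, config.vdj_length)
        for i in range(config.n_germlines)
    }
    heavy_names = list(heavy_germlines)
    light_names = list(light_germlines)

    sizes = _clone_sizes(rng, config.n_cells, config.clone_size_alpha)
    cells: list[CellRecord] = []
    truth: dict[str, CellTruth] = {}
    counter = 0
    span = config.cdr3_span

    for c_idx, size in enumerate(sizes):
        clone_id = f"clone_{c_idx + 1}"
        hv = heavy_names[int(rng.integers(0, len(heavy_names)))]
        lv = light_names[int(rng.integers(0, len(light_names)))]
        h_germ = heavy_germlines[hv]
        l_germ = light_germlines[lv]
        # members: (cell_id, stage t, heavy seq, light seq, subs_h, subs_l, switched, iso)
        members: list[tuple] = []
        for _ in range(size):
            cell_id = f"cell{counter:06d}"
            counter += 1
            t = int(rng.integers(0, config.max_shm_rounds + 1))
            eligible = [m for m in members if m[1] <= t]
            pick = int(rng.integers(0, len(eligible) + 1))  # == len(eligible) -> germline
            if pick == len(eligible):
                p_id, p_t, p_h, p_l = None, 0, h_germ, l_germ
                p_subs_h: list = []
                p_subs_l: list = []
                p_switched, p_iso = False, "IgM"
            else:
                p_id, p_t, p_h, p_l, p_subs_h, p_subs_l, p_switched, p_iso = eligible[pick]
            extra = t - p_t
            h_seq, new_h = _mutate(
                rng, p_h, extra, config.per_round_substitutions,
                config.mutation_strategy, mutation_provider,
            )
            extra_light = t // 2 - p_t // 2  # light chains mature at half the rounds
            l_seq, new_l = _mutate(
                rng, p_l, extra_light, config.per_round_substitutions,
                config.mutation_strategy, mutation_provider,
            )
            switched, iso = p_switched, p_iso
            for _ in range(extra):
                if not switched and rng.random() < config.switch_coupling:
                    switched = True
                    iso = "IgG" if rng.random() < 0.75 else "IgA"
            subs_h = p_subs_h + new_h
            subs_l = p_subs_l + new_l
            members.append((cell_id, t, h_seq, l_seq, subs_h, subs_l, switched, iso))
            isotype = iso if switched else "IgM"
            heavy = ChainRecord(
                cell_id=cell_id, locus="heavy", sequence_aa=h_seq, germline_aa=h_germ,
                v_call=f"{hv}-1*01", c_call=_ISOTYPE_C_CALL[isotype],
                cdr3_aa=h_seq[span[0]:span[1]], cdr3_span=span, sample_id="sim",
            )
            light = ChainRecord(
                cell_id=cell_id, locus="light", sequence_aa=l_seq, germline_aa=l_germ,
                v_call=f"{lv}-1*01", c_call="IGKC",
                cdr3_aa=l_seq[span[0]:span[1]], cdr3_span=span, sample_id="sim",
            )
            cells.append(CellRecord(cell_id=cell_id, heavy=heavy, light=light, sample_id="sim"))
            truth[cell_id] = CellTruth(
                clone_id=clone_id, parent_cell_id=p_id, rounds=t,
                substitutions_heavy=list(subs_h),
                substitutions_light=list(subs_l),
                switched=switched,
            )
    return SimulatedRepertoire(
        cells=cells, truth=truth,
        heavy_germlines=heavy_germlines, light_germlines=light_germlines,
        config=config,
    )


def replay_truth(sim: SimulatedRepertoire, cell_id: str, locus: str = "heavy") -> str:
    """Re-apply a cell's recorded substitutions to its germline; must reproduce its sequence."""
    cell = next(c for c in sim.cells if c.cell_id == cell_id)
    chain = cell.heavy if locus == "heavy" else cell.light
    t = sim.truth[cell_id]
    events = t.substitutions_heavy if locus == "heavy" else t.substitutions_light
    seq = list(chain.germline_aa)
    for pos, frm, to in events:
        if seq[pos] != frm:
            raise DataError(f"truth log inconsistent at position {pos}")
        seq[pos] = to
    return "".join(seq)


def simulate_affinity_table(
    sim: SimulatedRepertoire,
    coupling: float,
    noise_sd: float,
    seed: int,
    intercept: float = -8.0,
) -> pd.DataFrame:
    """Per-cell dissociation constants coupled to SHM load.

    ``log10(Kd) = intercept - coupling * SHM + N(0, noise_sd)`` with SHM the
    heavy-chain Hamming distance to germline, so positive coupling means more
    matured cells bind more strongly (lower Kd). The default intercept puts
    unmutated cells at Kd = 10 nM.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cell in sim.cells:
        shm = hamming_shm(cell.heavy.sequence_aa, cell.heavy.germline_aa)
        if shm is None:
            continue
        log_kd = intercept - coupling * shm + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"sequence_id": cell.cell_id, "kd": 10.0 ** log_kd, "shm": shm})
    return pd.DataFrame(rows)


def simulate_frequency_table(sim: SimulatedRepertoire, group_by: str = "v_family") -> pd.DataFrame:
    """Percent of unique heavy-chain sequences per group (OAS-style table).

    ``group_by`` is "v_family" or "isotype". Uniqueness is taken over
    (sequence, group) pairs; percentages sum to 100.
    """
    if not sim.cells:
        raise DataError("empty repertoire")
    if group_by not in ("v_family", "isotype"):
        raise DataError(f"unknown group_by {group_by!r}")
    pairs = set()
    for cell in sim.cells:
        group = v_family(cell.heavy.v_call) if group_by == "v_family" else cell.isotype
        pairs.add((cell.heavy.sequence_aa, group))
    counts: dict[str, int] = {}
    for _, group in pairs:
        counts[group] = counts.get(group, 0) + 1
    total = sum(counts.values())
    return pd.DataFrame(
        [{"group": g, "percent": 100.0 * n / total} for g, n in sorted(counts.items())]
    )
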