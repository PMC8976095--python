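# Nearest-neighbor helix stacking free energies, kcal/mol at 37 degC.
#
# Key "XY|WZ" means the pair X.Y (closing 5'X...Y3') stacked on the adjacent
# pair W.Z at positions i+1/j-1.  Watson-Crick entries follow the standard
# Turner/Xia parameter set; wobble (G.U) entries are rounded representative
# values.  Only one member of each mirror orbit is listed; the loader fills in
# the symmetric entry swap(WZ)|swap(XY) automatically.  Positive entries are
# clipped to 0: the engine treats stacking strictly as a bonus.
#
# version: 1
model_name: turner-stack-v1
min_hairpin_loop: 3
stacks:
  AU|AU: -0.93
  AU|UA: -1.10
  UA|AU: -1.33
  CG|AU: -2.11
  CG|UA: -2.08
  GC|AU: -2.35
  GC|UA: -2.24
  CG|GC: -2.36
  GC|CG: -3.42
  GC|GC: -3.26
  # wobble-containing stacks (rounded)
  AU|GU: -1.3
  AU|UG: -0.8
  UA|GU: -1.0
  UA|UG: -1.4
  CG|GU: -2.1
  CG|UG: -1.4
  GC|GU: -1.5
  GC|UG: -2.5
  GU|GU: -0.5
  GU|UG: -0.6
  UG|GU: 0.0
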