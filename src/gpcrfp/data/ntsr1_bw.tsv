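# Ballesteros-Weinstein table for rat NTSR1 (author numbering of the
# deposited crystal structures).  Explicit config: labels are transcribed
# residue by residue, never derived arithmetically from x.50 anchors.
#
# Ambiguity note: T231 has been labelled both 5.32 and 5.33 in the
# literature describing these structures.  This table uses 5.32, which is
# consistent with the helix-5 anchor P249 = 5.50; analyses addressing the
# residue by number are unaffected.
#
# Membrane-half assignment uses a per-helix midplane boundary residue
# (the x.50 connector/microswitch level for TM3/5/6, the 7.45 level for
# TM7); residues at the boundary are assigned to the extracellular side.
# Helix ranges are approximate TM spans in author numbering.
#range 1 64 90
#range 2 99 124
#range 3 143 172
#range 4 178 202
#range 5 225 270
#range 6 297 334
#range 7 343 372
seq_number	bw_label	helix_id	half
86	1.54	1	intracellular
146	3.29	3	extracellular
149	3.32	3	extracellular
156	3.39	3	extracellular
157	3.40	3	extracellular
160	3.43	3	intracellular
164	3.47	3	intracellular
166	3.49	3	intracellular
167	3.50	3	intracellular
208	ECL2.208	loop	extracellular
215	ECL2.215	loop	extracellular
216	ECL2.216	loop	extracellular
219	ECL2.219	loop	extracellular
231	5.32	5	extracellular
241	5.42	5	extracellular
245	5.46	5	extracellular
249	5.50	5	extracellular
257	5.58	5	intracellular
268	5.69	5	intracellular
300	6.27	6	intracellular
303	6.30	6	intracellular
310	6.37	6	intracellular
317	6.44	6	intracellular
321	6.48	6	extracellular
324	6.51	6	extracellular
327	6.54	6	extracellular
328	6.55	6	extracellular
331	6.58	6	extracellular
332	6.59	6	extracellular
347	7.31	7	extracellular
351	7.35	7	extracellular
358	7.42	7	extracellular
359	7.43	7	extracellular
360	7.44	7	extracellular
369	7.53	7	intracellular
372	7.56	7	intracellular
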