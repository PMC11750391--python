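enzyme,kind,substrate,product,conversion,activity_label
Elovl6-like A,elongase,18:2n-6,20:2n-6,0.5,C18→C20
Elovl6-like A,elongase,18:3n-3,20:3n-3,0.4,C18→C20
Elovl6-like A,elongase,18:3n-6,20:3n-6,0.4,C18→C20
Elovl6-like A,elongase,18:4n-3,20:4n-3,0.6,C18→C20
Elovl6-like A,elongase,20:4n-6,22:4n-6,n.d.,C20→C22
Elovl6-like A,elongase,20:5n-3,22:5n-3,n.d.,C20→C22
Elovl6-like A,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like A,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like B,elongase,18:2n-6,20:2n-6,1.5,C18→C20
Elovl6-like B,elongase,18:3n-3,20:3n-3,2.4,C18→C20
Elovl6-like B,elongase,18:3n-6,20:3n-6,0.5,C18→C20
Elovl6-like B,elongase,18:4n-3,20:4n-3,0.9,C18→C20
Elovl6-like B,elongase,20:4n-6,22:4n-6,n.d.,C20→C22
Elovl6-like B,elongase,20:5n-3,22:5n-3,n.d.,C20→C22
Elovl6-like B,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like B,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like C,elongase,18:2n-6,20:2n-6,48.0,C18→C20
Elovl6-like C,elongase,18:3n-3,20:3n-3,58.5,C18→C20
Elovl6-like C,elongase,18:3n-6,20:3n-6,39.7,C18→C20
Elovl6-like C,elongase,18:4n-3,20:4n-3,41.4,C18→C20
Elovl6-like C,elongase,20:4n-6,22:4n-6,1.6,C20→C22
Elovl6-like C,elongase,20:5n-3,22:5n-3,1.4,C20→C22
Elovl6-like C,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like C,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like C,elongase,16:1n-7,18:1n-7,qual,C16→C18
Elovl6-like C,elongase,18:1n-7,20:1n-7,qual,C18→C20
Elovl6-like C,elongase,18:1n-9,20:1n-9,qual,C18→C20
Elovl6-like D,elongase,18:2n-6,20:2n-6,1.2,C18→C20
Elovl6-like D,elongase,18:3n-3,20:3n-3,1.6,C18→C20
Elovl6-like D,elongase,18:3n-6,20:3n-6,0.8,C18→C20
Elovl6-like D,elongase,18:4n-3,20:4n-3,1.2,C18→C20
Elovl6-like D,elongase,20:4n-6,22:4n-6,0.1,C20→C22
Elovl6-like D,elongase,20:5n-3,22:5n-3,0.3,C20→C22
Elovl6-like D,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like D,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like E,elongase,18:2n-6,20:2n-6,0.7,C18→C20
Elovl6-like E,elongase,18:3n-3,20:3n-3,1.6,C18→C20
Elovl6-like E,elongase,18:3n-6,20:3n-6,0.6,C18→C20
Elovl6-like E,elongase,18:4n-3,20:4n-3,1.0,C18→C20
Elovl6-like E,elongase,20:4n-6,22:4n-6,n.d.,C20→C22
Elovl6-like E,elongase,20:5n-3,22:5n-3,0.6,C20→C22
Elovl6-like E,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like E,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like F,elongase,18:2n-6,20:2n-6,0.4,C18→C20
Elovl6-like F,elongase,18:3n-3,20:3n-3,0.5,C18→C20
Elovl6-like F,elongase,18:3n-6,20:3n-6,0.4,C18→C20
Elovl6-like F,elongase,18:4n-3,20:4n-3,0.5,C18→C20
Elovl6-like F,elongase,20:4n-6,22:4n-6,n.d.,C20→C22
Elovl6-like F,elongase,20:5n-3,22:5n-3,n.d.,C20→C22
Elovl6-like F,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like F,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like G,elongase,18:2n-6,20:2n-6,3.7,C18→C20
Elovl6-like G,elongase,18:3n-3,20:3n-3,1.2,C18→C20
Elovl6-like G,elongase,18:3n-6,20:3n-6,1.2,C18→C20
Elovl6-like G,elongase,18:4n-3,20:4n-3,0.8,C18→C20
Elovl6-like G,elongase,20:4n-6,22:4n-6,0.4,C20→C22
Elovl6-like G,elongase,20:5n-3,22:5n-3,0.5,C20→C22
Elovl6-like G,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like G,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl6-like H,elongase,18:2n-6,20:2n-6,0.7,C18→C20
Elovl6-like H,elongase,18:3n-3,20:3n-3,2.4,C18→C20
Elovl6-like H,elongase,18:3n-6,20:3n-6,0.5,C18→C20
Elovl6-like H,elongase,18:4n-3,20:4n-3,0.6,C18→C20
Elovl6-like H,elongase,20:4n-6,22:4n-6,n.d.,C20→C22
Elovl6-like H,elongase,20:5n-3,22:5n-3,n.d.,C20→C22
Elovl6-like H,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl6-like H,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl2/5-like,elongase,18:2n-6,20:2n-6,1.6,C18→C20
Elovl2/5-like,elongase,18:3n-3,20:3n-3,2.5,C18→C20
Elovl2/5-like,elongase,18:3n-6,20:3n-6,3.4,C18→C20
Elovl2/5-like,elongase,18:4n-3,20:4n-3,5.7,C18→C20
Elovl2/5-like,elongase,20:4n-6,22:4n-6,3.1,C20→C22
Elovl2/5-like,elongase,20:5n-3,22:5n-3,3.7,C20→C22
Elovl2/5-like,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl2/5-like,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl-like,elongase,18:2n-6,20:2n-6,1.1,C18→C20
Elovl-like,elongase,18:3n-3,20:3n-3,0.2,C18→C20
Elovl-like,elongase,18:3n-6,20:3n-6,0.6,C18→C20
Elovl-like,elongase,18:4n-3,20:4n-3,0.4,C18→C20
Elovl-like,elongase,20:4n-6,22:4n-6,0.2,C20→C22
Elovl-like,elongase,20:5n-3,22:5n-3,0.4,C20→C22
Elovl-like,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl-like,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl1/7-like,elongase,18:2n-6,20:2n-6,3.4,C18→C20
Elovl1/7-like,elongase,18:3n-3,20:3n-3,1.9,C18→C20
Elovl1/7-like,elongase,18:3n-6,20:3n-6,8.6,C18→C20
Elovl1/7-like,elongase,18:4n-3,20:4n-3,3.0,C18→C20
Elovl1/7-like,elongase,20:4n-6,22:4n-6,21.7,C20→C22
Elovl1/7-like,elongase,20:5n-3,22:5n-3,11.6,C20→C22
Elovl1/7-like,elongase,22:4n-6,24:4n-6,9.5,C22→C24
Elovl1/7-like,elongase,22:5n-3,24:5n-3,14.7,C22→C24
Elovl4-like,elongase,18:2n-6,20:2n-6,0.6,C18→C20
Elovl4-like,elongase,18:3n-3,20:3n-3,0.7,C18→C20
Elovl4-like,elongase,18:3n-6,20:3n-6,0.7,C18→C20
Elovl4-like,elongase,18:4n-3,20:4n-3,0.8,C18→C20
Elovl4-like,elongase,20:4n-6,22:4n-6,0.4,C20→C22
Elovl4-like,elongase,20:5n-3,22:5n-3,0.9,C20→C22
Elovl4-like,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl4-like,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
Elovl8-like,elongase,18:2n-6,20:2n-6,1.5,C18→C20
Elovl8-like,elongase,18:3n-3,20:3n-3,3.9,C18→C20
Elovl8-like,elongase,18:3n-6,20:3n-6,0.8,C18→C20
Elovl8-like,elongase,18:4n-3,20:4n-3,0.7,C18→C20
Elovl8-like,elongase,20:4n-6,22:4n-6,2.0,C20→C22
Elovl8-like,elongase,20:5n-3,22:5n-3,1.7,C20→C22
Elovl8-like,elongase,22:4n-6,24:4n-6,n.d.,C22→C24
Elovl8-like,elongase,22:5n-3,24:5n-3,n.d.,C22→C24
FadsA,desaturase,18:2n-6,18:3n-6,n.d.,Δ6
FadsA,desaturase,18:3n-3,18:4n-3,n.d.,Δ6
FadsA,desaturase,20:2n-6,20:3n-6,n.d.,Δ8
FadsA,desaturase,20:3n-3,20:4n-3,n.d.,Δ8
FadsA,desaturase,20:3n-6,20:4n-6,50.2,Δ5
FadsA,desaturase,20:4n-3,20:5n-3,34.7,Δ5
FadsA,desaturase,22:4n-6,22:5n-6,n.d.,Δ4
FadsA,desaturase,22:5n-3,22:6n-3,n.d.,Δ4
FadsA,desaturase,20:1n-9,"20:2^Δ5,11^",35.1,Δ5
FadsA,desaturase,20:1n-7,"20:2^Δ5,13^",29.7,Δ5
FadsA,desaturase,20:2n-6,"20:3^Δ5,11,14^",28.9,Δ5
FadsA,desaturase,20:3n-3,"20:4^Δ5,11,14,17^",14.5,Δ5
FadsA,desaturase,18:0,18:1n-13,qual,Δ5
FadsC1,desaturase,18:2n-6,18:3n-6,n.d.,Δ6
FadsC1,desaturase,18:3n-3,18:4n-3,n.d.,Δ6
FadsC1,desaturase,20:2n-6,20:3n-6,n.d.,Δ8
FadsC1,desaturase,20:3n-3,20:4n-3,0.2,Δ8
FadsC1,desaturase,20:3n-6,20:4n-6,n.d.,Δ5
FadsC1,desaturase,20:4n-3,20:5n-3,n.d.,Δ5
FadsC1,desaturase,22:4n-6,22:5n-6,n.d.,Δ4
FadsC1,desaturase,22:5n-3,22:6n-3,n.d.,Δ4
FadsC2,desaturase,18:2n-6,18:3n-6,0.5,Δ6
FadsC2,desaturase,18:3n-3,18:4n-3,0.1,Δ6
FadsC2,desaturase,20:2n-6,20:3n-6,40.5,Δ8
FadsC2,desaturase,20:3n-3,20:4n-3,11.7,Δ8
FadsC2,desaturase,20:3n-6,20:4n-6,n.d.,Δ5
FadsC2,desaturase,20:4n-3,20:5n-3,n.d.,Δ5
FadsC2,desaturase,22:4n-6,22:5n-6,n.d.,Δ4
FadsC2,desaturase,22:5n-3,22:6n-3,n.d.,Δ4
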