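# Herbs preserving and strengthening the requisite energy (Bomyeongjiju),
# stratified by Sasang constitution type. TY herbs derive from the two
# prescriptions specified for that type; Pruni Arillus is excluded
# (absent from the compound-target source database).
herb_id	group	local_name	latin_name
H01	SE	Insam (renshen)	Ginseng Radix
H02	SE	Baekchul (baizhu)	Atractylodis Rhizoma Alba
H03	SE	Jagamcho (zhigancao)	Glycyrrhizae Radix et Rhizoma Praeparata cum Melle
H04	SE	Danggui (danggui)	Angelicae Gigantis Radix
H05	SE	Chungung (chuanxiong)	Cnidii Rhizoma
H06	SE	Gwangye (guangui)	Cortex Cinnamomi
H07	SE	Jinpi (chenpi)	Citri Unshius Pericarpium
H08	SE	Baekjakyak (baishaoyao)	Paeoniae Radix
H09	SY	Sugjihwang (shudihuang)	Rehmanniae Radix Preparata
H10	SY	Sansuyu (shanzhuyu)	Corni Fructus
H11	SY	Bokryeong (fufing)	Poria Sclerotium
H12	SY	Jimo (zhimu)	Anemarrhenae Rhizoma
H13	SY	Taegsa (zexie)	Alismatis Rhizoma
H14	SY	Moktong (mutong)	Akebiae Caulis
H15	SY	Mokdanpi (mudanpi)	Moutan Radicis Cortex
H16	SY	Huangbaek (huangbai)	Phellodendri Cortex
H17	TE	Maengmundong (maimendong)	Liriopis seu Ophiopogonis Tuber
H18	TE	Omija (wuweizi)	Schisandrae Fructus
H19	TE	Sadang (shatang)	Saccharum
H20	TE	Sanyak (shanyao)	Dioscoreae Rhizoma
H21	TE	Gilgyeong (jiegeng)	Platycodonis Radix
H22	TE	Uwang (niuhuang)	Bostaurus Linne var. domesticus Gmelin
H23	TE	Seokchangpo (shichangpu)	Acori Graminei Rhizoma
H24	TE	Hunaggeum (huangqin)	Scutellariae Radix
H25	TY	Ogapi (wejiapi)	Acanthopanacis Cortex
H26	TY	Mogwa (mugua)	Chaenomelis Fructus
H27	TY	Podogeun (putaogen)	Radix Vitis Romanetii
H28	TY	Nogeun (lugen)	Phragmitis Rhizoma
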