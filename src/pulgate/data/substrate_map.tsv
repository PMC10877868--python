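family	substrates
GH3	beta-1,3-glucan
GH16	beta-1,3-glucan
GH17	beta-1,3-glucan
GH30	beta-1,3-glucan
GH149	beta-1,3-glucan
GH158	beta-1,3-glucan
GH13	alpha-glucan
GH31	alpha-glucan
GH57	alpha-glucan
GH65	alpha-glucan
GH77	alpha-glucan
GH133	alpha-glucan
PL6	alginate
PL7	alginate
PL15	alginate
PL17	alginate
PL18	alginate
PL34	alginate
PL36	alginate
GH29	fucoidan
GH95	fucoidan
GH107	fucoidan
GH141	fucoidan
CE17	fucoidan
GH33	sialic-acid
GH18	chitin
GH19	chitin
GH20	chitin
CE4	chitin
GH8	xylan
GH10	xylan
GH11	xylan
GH67	xylan
GH115	xylan
GH120	xylan
CE1	xylan
CE2	xylan
CE3	xylan
CE6	xylan
CE7	xylan
GH43	xylan;arabinan
GH51	arabinan
GH54	arabinan
GH93	arabinan
GH78	alpha-rhamnoside
GH106	alpha-rhamnoside
GH26	beta-mannan
GH113	beta-mannan
GH134	beta-mannan
GH38	alpha-mannan
GH76	alpha-mannan
GH92	alpha-mannan
GH99	alpha-mannan
GH125	alpha-mannan
GH28	pectin
GH105	pectin
PL1	pectin
PL2	pectin
PL9	pectin
PL10	pectin
PL11	pectin
PL22	pectin
PL26	pectin
CE8	pectin
CE12	pectin
GH23	peptidoglycan
GH24	peptidoglycan
GH25	peptidoglycan
GH73	peptidoglycan
GH102	peptidoglycan
GH103	peptidoglycan
GH104	peptidoglycan
GH5	cellulose
GH6	cellulose
GH9	cellulose
GH12	cellulose
GH44	cellulose
GH45	cellulose
GH48	cellulose
GH84	host-glycan
GH85	host-glycan
GH89	host-glycan
GH98	host-glycan
GH101	host-glycan
GH109	host-glycan
GH110	host-glycan
GH129	host-glycan
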