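food_id,name,group,serving_desc,serving_g,kcal,cho_g,protein_g,fat_g,fiber_g,glycemic_index,diabetes_suitable,regional
tortilla_maiz,Tortilla de maiz,cereal_tuber,1 pieza,30,64,13.6,1.4,0.5,1.8,52,true,true
bolillo_medio,Medio bolillo,cereal_tuber,1/2 pieza,35,62,12.0,2.0,0.4,0.7,70,false,true
arroz_cocido,Arroz cocido,cereal_tuber,1/2 taza,80,98,22.0,2.0,0.2,0.6,64,false,true
avena_cruda,Avena en hojuelas,cereal_tuber,1/3 taza,30,106,18.0,4.0,2.0,2.8,55,true,false
papa_cocida,Papa cocida,cereal_tuber,1 pieza chica,100,89,20.0,2.0,0.1,1.8,78,false,true
camote_cocido,Camote cocido,cereal_tuber,3/4 taza,75,65,15.0,1.0,0.1,2.3,63,false,true
elote_cocido,Elote cocido,cereal_tuber,1/2 pieza,90,97,19.0,3.0,1.0,2.5,52,true,true
pan_integral,Pan integral,cereal_tuber,1 rebanada,28,69,12.0,3.0,1.0,1.9,51,true,false
frijol_negro_cocido,Frijol negro cocido,legume,1/2 taza,86,112,20.0,7.0,0.5,7.5,30,true,true
lenteja_cocida,Lenteja cocida,legume,1/2 taza,99,120,20.0,9.0,0.4,7.8,29,true,true
garbanzo_cocido,Garbanzo cocido,legume,1/2 taza,82,134,22.0,7.0,2.0,6.2,28,true,true
haba_cocida,Haba cocida,legume,1/2 taza,85,97,17.0,6.5,0.3,4.6,32,true,true
nopales_cocidos,Nopales cocidos,vegetable,1 taza,149,29,5.0,2.0,0.1,3.0,7,true,true
calabacita_cocida,Calabacita cocida,vegetable,1 taza,113,24,4.0,1.5,0.2,1.4,15,true,true
espinaca_cocida,Espinaca cocida,vegetable,1/2 taza,90,26,3.4,2.7,0.2,2.2,15,true,true
chayote_cocido,Chayote cocido,vegetable,1/2 taza,80,20,4.0,0.5,0.2,1.8,24,true,true
jitomate_crudo,Jitomate crudo,vegetable,1 pieza,120,25,4.7,1.0,0.2,1.4,15,true,true
zanahoria_cruda,Zanahoria cruda,vegetable,1/2 taza,64,27,6.0,0.6,0.1,1.8,39,true,true
chile_poblano,Chile poblano asado,vegetable,1 pieza,85,28,5.0,1.5,0.2,2.1,15,true,true
verdolagas_cocidas,Verdolagas cocidas,vegetable,1/2 taza,58,13,2.0,0.9,0.1,0.9,10,true,true
papaya_picada,Papaya picada,fruit,1 taza,140,66,15.0,0.7,0.4,2.5,59,true,true
platano_tabasco,Platano tabasco,fruit,1/2 pieza,60,61,14.0,0.7,0.2,1.6,51,true,true
naranja_entera,Naranja entera,fruit,1 pieza,130,67,15.0,1.2,0.2,3.1,43,true,true
mango_manila,Mango manila,fruit,1/2 pieza,104,73,17.0,0.6,0.3,1.9,51,true,true
sandia_picada,Sandia picada,fruit,1 taza,152,51,11.5,0.9,0.2,0.6,76,false,true
guayaba,Guayaba,fruit,2 piezas,110,62,13.0,1.5,0.5,5.9,29,true,true
pollo_asado,Pollo asado sin piel,animal_protein,30 g,40,48,0.0,8.5,1.5,0.0,,true,true
huevo_entero,Huevo entero,animal_protein,1 pieza,50,73,0.6,6.3,5.0,0.0,,true,true
pescado_mojarra,Mojarra asada,animal_protein,30 g,40,41,0.0,8.0,1.0,0.0,,true,true
res_magra,Carne de res magra,animal_protein,30 g,40,57,0.0,8.5,2.5,0.0,,true,true
cerdo_lomo,Lomo de cerdo,animal_protein,30 g,40,51,0.0,8.3,2.0,0.0,,true,true
camaron_cocido,Camaron cocido,animal_protein,45 g,45,42,0.4,9.0,0.5,0.0,,true,true
leche_descremada,Leche descremada,dairy,1 taza,244,83,12.0,8.3,0.2,0.0,32,true,true
queso_fresco,Queso fresco,dairy,40 g,40,105,1.2,7.0,8.0,0.0,27,true,true
yogurt_natural,Yogurt natural,dairy,1 taza,245,112,11.0,8.5,3.8,0.0,36,true,false
queso_panela,Queso panela,dairy,40 g,40,98,1.5,9.5,6.0,0.0,27,true,true
aguacate,Aguacate,fats_oils,1/3 pieza,50,89,4.3,1.0,7.5,3.4,15,true,true
aceite_vegetal,Aceite vegetal,fats_oils,1 cucharadita,5,45,0.0,0.0,5.0,0.0,,true,false
cacahuate_tostado,Cacahuate tostado,fats_oils,14 g,14,86,2.2,3.6,7.0,1.2,14,true,true
pepita_calabaza,Pepita de calabaza,fats_oils,10 g,10,60,1.1,3.0,4.9,0.6,25,true,true
crema_acida,Crema acida,fats_oils,1 cucharada,15,49,0.6,0.4,5.0,0.0,,false,true
azucar_mesa,Azucar de mesa,sugar_sweet,1 cucharadita,4,16,4.0,0.0,0.0,0.0,65,false,false
miel_abeja,Miel de abeja,sugar_sweet,1 cucharadita,7,23,5.8,0.0,0.0,0.0,61,false,true
pan_dulce_concha,Media concha,sugar_sweet,1/2 pieza,30,108,17.0,2.0,3.5,0.6,70,false,true
refresco_cola,Refresco de cola,sugar_sweet,1/2 taza,120,52,13.0,0.0,0.0,0.0,63,false,false
atole_maiz,Atole de maiz,sugar_sweet,1/2 taza,120,73,15.0,1.5,0.8,0.4,65,false,true
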